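"""Imputation, PCA, group statistics, and confidence ellipses."""

import math

import numpy as np
import pandas as pd
import pytest

from idrisle.niche import (
    confidence_ellipse,
    group_compare,
    mice_impute,
    pca,
    presence_labels,
)


class TestMiceImpute:
    def test_complete_data_returned_unchanged(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [2.0, 1.0, 0.0]})
        assert mice_impute(df).equals(df)

    def test_exact_linear_relation_recovered(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "y": [2.0, 4.0, np.nan, 8.0]})
        out = mice_impute(df)
        assert out.at[2, "y"] == pytest.approx(6.0, abs=1e-5)

    def test_observed_cells_never_altered(self):
        rng = np.random.default_rng(0)
        base = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        masked = base.copy()
        holes = rng.random(base.shape) < 0.15
        masked = masked.mask(holes)
        out = mice_impute(masked)
        observed = ~holes
        assert np.allclose(out.to_numpy()[observed], base.to_numpy()[observed])

    def test_beats_column_mean_imputation_on_linear_structure(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=80)
        df_true = pd.DataFrame(
            {
                "a": x,
                "b": 2 * x + rng.normal(scale=0.1, size=80),
                "c": -x + rng.normal(scale=0.1, size=80),
            }
        )
        masked = df_true.copy()
        holes = rng.random(df_true.shape) < 0.10
        masked = masked.mask(holes)
        out = mice_impute(masked)
        mean_filled = masked.fillna(masked.mean())
        truth = df_true.to_numpy()[holes]
        rmse_mice = np.sqrt(np.mean((out.to_numpy()[holes] - truth) ** 2))
        rmse_mean = np.sqrt(np.mean((mean_filled.to_numpy()[holes] - truth) ** 2))
        assert rmse_mice < rmse_mean

    def test_column_with_too_few_observations_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [np.nan, np.nan, 1.0]})
        with pytest.raises(ValueError):
            mice_impute(df)


class TestPca:
    def test_collinear_data_is_rank_one(self):
        x = np.arange(1.0, 9.0)
        df = pd.DataFrame({"x": x, "y": 2 * x})
        result = pca(df)
        assert result.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_variance_ratios_sum_to_one(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(40, 6)))
        assert pca(df).explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(30, 5)))
        L = pca(df).loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)

    def test_matches_hand_eigendecomposition(self):
        """Independent oracle: eigendecompose the correlation matrix of a
        small hand-built table and compare variance ratios and loadings."""
        df = pd.DataFrame(
            {"a": [1.0, 2.0, 4.0, 5.0], "b": [0.5, 1.0, 3.0, 2.5], "c": [9.0, 7.0, 3.0, 1.0]}
        )
        result = pca(df)
        z = (df - df.mean()) / df.std(ddof=0)
        corr = z.to_numpy().T @ z.to_numpy() / len(df)
        eigvals, eigvecs = np.linalg.eigh(corr)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = np.clip(eigvals[order], 0, None), eigvecs[:, order]
        assert np.allclose(
            result.explained_variance_ratio, eigvals / eigvals.sum(), atol=1e-8
        )
        for j in range(3):
            dot = abs(result.loadings.to_numpy()[:, j] @ eigvecs[:, j])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(25, 4)))
        L = pca(df).loadings.to_numpy()
        for j in range(L.shape[1]):
            assert L[np.abs(L[:, j]).argmax(), j] > 0

    def test_zero_variance_column_named(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "flat": [7.0, 7.0, 7.0]})
        with pytest.raises(ValueError, match="flat"):
            pca(df)

    def test_missing_values_rejected(self):
        df = pd.DataFrame({"x": [1.0, np.nan, 3.0], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            pca(df)


class TestGroupCompare:
    def test_identical_groups_identical_stats(self):
        stats = group_compare([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        a, b = stats["a"], stats["b"]
        assert (a.n, a.mean, a.median, a.ci_low, a.ci_high) == (
            b.n, b.mean, b.median, b.ci_low, b.ci_high
        )

    def test_hand_medians(self):
        stats = group_compare([10, 20, 30, 40], ["present", "present", "absent", "absent"])
        assert stats["present"].median == 15
        assert stats["absent"].median == 35

    def test_singleton_group_has_degenerate_ci(self):
        stats = group_compare([5.0, 1.0, 2.0], ["solo", "rest", "rest"])
        assert stats["solo"].ci_low == stats["solo"].ci_high == 5.0

    def test_ci_contains_mean_and_tightens_with_n(self):
        rng = np.random.default_rng(6)
        small = group_compare(rng.normal(size=10), ["g"] * 10)["g"]
        big = group_compare(rng.normal(size=1000), ["g"] * 1000)["g"]
        assert small.ci_low <= small.mean <= small.ci_high
        assert (big.ci_high - big.ci_low) < (small.ci_high - small.ci_low)

    def test_empty_values_rejected(self):
        with pytest.raises(ValueError):
            group_compare([], [])


class TestConfidenceEllipse:
    def test_isotropic_cloud_has_near_equal_axes(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(4000, 2))
        ell = confidence_ellipse(pts, ["g"] * 4000)["g"]
        a, b = ell.semi_axes
        assert b / a > 0.9  # within 10 %

    def test_degenerate_identical_points_have_zero_axes(self):
        pts = np.ones((5, 2))
        ell = confidence_ellipse(pts, ["g"] * 5)["g"]
        assert ell.semi_axes == (0.0, 0.0)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(200, 2)) * np.array([3.0, 0.5])
        rot = pts @ np.array([[0.0, -1.0], [1.0, 0.0]]).T  # 90 degrees
        e0 = confidence_ellipse(pts, ["g"] * 200)["g"]
        e1 = confidence_ellipse(rot, ["g"] * 200)["g"]
        assert e1.semi_axes == pytest.approx(e0.semi_axes)
        delta = abs(e1.angle_rad - e0.angle_rad) % math.pi
        assert min(delta, math.pi - delta) == pytest.approx(math.pi / 2, abs=1e-6)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            confidence_ellipse(np.ones((2, 2)), ["g", "g"])


class TestPresenceLabels:
    def test_three_level_grouping(self):
        labels = presence_labels({"s1": 0, "s2": 1, "s3": 4})
        assert labels.tolist() == ["absent", "single_hit", "multiple_hits"]
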