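"""Marker-presence vs geochemistry statistics.

Associates marker presence with the ten-variable sample metadata table:
deterministic chained-equation imputation (MICE) of missing cells,
correlation-matrix PCA with oriented loadings and explained variance,
per-group summary statistics with t-based confidence intervals, and
1-standard-deviation covariance ellipses in principal-component space.

The MICE variant here is deliberately deterministic — regression
prediction without posterior draws — so that imputation is exactly
reproducible; all samples enter the PCA regardless of marker presence,
with presence labels used only for grouping downstream.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA as _SkPCA

PRESENCE_LEVELS = ("absent", "single_hit", "multiple_hits")


def presence_labels(n_hits: Mapping[str, int]) -> pd.Series:
    """Three-level presence grouping from per-sample hit counts."""
    return pd.Series(
        {
            sid: ("absent" if n == 0 else "single_hit" if n == 1 else "multiple_hits")
            for sid, n in n_hits.items()
        },
        name="presence",
    )


# ---------------------------------------------------------------------------
# MICE


def mice_impute(
    matrix: pd.DataFrame,
    max_iter: int = 20,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Deterministic multivariate imputation by chained equations.

    Missing cells start at their column means; columns are then cycled in
    fixed (input) order, each regressed by ordinary least squares on all
    other columns over its originally-observed rows, and its missing cells
    overwritten with the regression predictions.  Iteration stops when the
    largest absolute cell change drops below ``tol``.  Observed cells are
    never altered.
    """
    data = matrix.astype(float).copy()
    observed = data.notna()
    if observed.all().all():
        return data
    fully_missing = observed.sum(axis=0) < 2
    if fully_missing.any():
        bad = list(data.columns[fully_missing])
        raise ValueError(f"columns with fewer than 2 observed values: {bad}")
    empty_rows = (~observed).all(axis=1)
    if empty_rows.any():
        raise ValueError(f"fully-missing rows: {list(data.index[empty_rows])}")

    # mean initialization
    for col in data.columns:
        data.loc[~observed[col], col] = data.loc[observed[col], col].mean()

    values = data.to_numpy()
    obs = observed.to_numpy()
    n, p = values.shape
    for _ in range(max_iter):
        max_change = 0.0
        for j in range(p):
            missing_j = ~obs[:, j]
            if not missing_j.any():
                continue
            others = [k for k in range(p) if k != j]
            X_obs = np.column_stack([np.ones(obs[:, j].sum()), values[obs[:, j]][:, others]])
            y_obs = values[obs[:, j], j]
            beta, *_ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
            X_mis = np.column_stack([np.ones(missing_j.sum()), values[missing_j][:, others]])
            pred = X_mis @ beta
            max_change = max(max_change, float(np.abs(pred - values[missing_j, j]).max()))
            values[missing_j, j] = pred
        if max_change < tol:
            break
    return pd.DataFrame(values, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PcaResult:
    """Standardized-variable PCA: scores, unit-norm loadings, variance ratios."""

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # variables x components
    explained_variance_ratio: np.ndarray

    def __post_init__(self) -> None:
        r = self.explained_variance_ratio
        if (r < -1e-12).any() or r.max() > 1 + 1e-12:
            raise ValueError("variance ratios must lie in [0, 1]")


def pca(matrix: pd.DataFrame) -> PcaResult:
    """Correlation-matrix PCA of a complete environmental table.

    Columns are standardized to zero mean and unit variance (mixed units
    make covariance PCA meaningless here), then decomposed by SVD.  Each
    loading column is oriented so its largest-magnitude entry is positive,
    fixing the sign indeterminacy.
    """
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values; impute first")
    if len(matrix) < 3:
        raise ValueError("PCA needs at least 3 samples")
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=0)
    zero_var = np.flatnonzero(sd == 0)
    if zero_var.size:
        raise ValueError(f"zero-variance column: {matrix.columns[zero_var[0]]!r}")
    z = (values - values.mean(axis=0)) / sd

    model = _SkPCA(n_components=min(matrix.shape))
    scores = model.fit_transform(z)
    loadings = model.components_.T  # variables x components, unit-norm columns

    # orient: largest |loading| in each component is positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = scores * flip

    comp_names = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=matrix.columns, columns=comp_names),
        explained_variance_ratio=model.explained_variance_ratio_.copy(),
    )


# ---------------------------------------------------------------------------
# Group statistics


@dataclass(frozen=True)
class GroupStats:
    group: str
    n: int
    mean: float
    median: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group must contain at least one sample")
        if not (self.ci_low - 1e-12 <= self.mean <= self.ci_high + 1e-12):
            raise ValueError("confidence interval must contain the mean")


def group_compare(
    values: Sequence[float] | pd.Series,
    labels: Sequence[str] | pd.Series,
    confidence: float = 0.95,
) -> dict[str, GroupStats]:
    """Mean, median, and t-based CI of one variable per presence group."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if values.shape != labels.shape:
        raise ValueError("values and labels must align")
    if values.size == 0:
        raise ValueError("no samples supplied")
    out: dict[str, GroupStats] = {}
    for group in sorted(set(labels)):
        v = values[labels == group]
        if v.size == 0:
            raise ValueError(f"empty group {group!r}")
        mean = float(v.mean())
        if v.size == 1:
            lo = hi = mean
        else:
            sem = float(v.std(ddof=1) / math.sqrt(v.size))
            tcrit = float(stats.t.ppf(0.5 + confidence / 2, df=v.size - 1))
            lo, hi = mean - tcrit * sem, mean + tcrit * sem
        out[group] = GroupStats(
            group=group, n=int(v.size), mean=mean, median=float(np.median(v)), ci_low=lo, ci_high=hi
        )
    return out


# ---------------------------------------------------------------------------
# Confidence ellipses


@dataclass(frozen=True)
class Ellipse:
    """1-SD covariance ellipse of a group's scores in a 2-D plane."""

    group: str
    center: tuple[float, float]
    semi_axes: tuple[float, float]  # major, minor
    angle_rad: float  # of the major axis, in (-pi/2, pi/2]

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.semi_axes):
            raise ValueError("semi-axes must be >= 0")


def confidence_ellipse(
    scores: pd.DataFrame | np.ndarray,
    labels: Sequence[str] | pd.Series,
) -> dict[str, Ellipse]:
    """1-standard-deviation ellipse per group from 2-D scores.

    Center = group mean; semi-axes = square roots of the group covariance
    eigenvalues; angle = orientation of the leading eigenvector.  Groups
    with fewer than 3 samples are rejected.
    """
    pts = scores.to_numpy(dtype=float) if isinstance(scores, pd.DataFrame) else np.asarray(scores, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("scores must be n x 2")
    labels = np.asarray(labels, dtype=object)
    if labels.shape[0] != pts.shape[0]:
        raise ValueError("labels must align with scores")
    out: dict[str, Ellipse] = {}
    for group in sorted(set(labels)):
        p = pts[labels == group]
        if p.shape[0] < 3:
            raise ValueError(f"group {group!r} has fewer than 3 samples")
        center = p.mean(axis=0)
        cov = np.cov(p, rowvar=False, ddof=1)
        eigvals, eigvecs = np.linalg.eigh(cov)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        eigvals = np.clip(eigvals, 0.0, None)
        major = eigvecs[:, 0]
        angle = math.atan2(major[1], major[0])
        if angle <= -math.pi / 2:
            angle += math.pi
        elif angle > math.pi / 2:
            angle -= math.pi
        out[group] = Ellipse(
            group=group,
            center=(float(center[0]), float(center[1])),
            semi_axes=(float(math.sqrt(eigvals[0])), float(math.sqrt(eigvals[1]))),
            angle_rad=angle,
        )
    return out
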