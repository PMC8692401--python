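"""Position-specific log-odds marker model and adjacency-calibrated threshold.

The iodate-reductase catalytic subunit is detected with a position-specific
scoring matrix (PSSM) built from aligned family members: per-column residue
probabilities with a pseudocount, log-odds in bits against a background
distribution, and a best-ungapped-placement score for query proteins.
Sequences shorter than the fragment filter (280 residues) are reported as
filtered rather than scored.

The hit threshold is not fixed a priori: it is calibrated so that every
genome whose marker neighborhood lacks the peroxidase pair (an arsenite-
oxidase-like locus) falls below it — the same exclusion rule used to set
the published HMM cutoff, formalized as max(non-adjacent score) + delta.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}
#: floor for log-odds of zero-probability cells, bits
LOG_ODDS_FLOOR = -20.0
DEFAULT_MIN_LENGTH = 280


@dataclass
class ProfileModel:
    """Ungapped log-odds profile over the 20-letter amino-acid alphabet."""

    log_odds: np.ndarray  # (length, 20), bits
    background: np.ndarray  # (20,), sums to 1
    alpha: float

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.log_odds.ndim != 2 or self.log_odds.shape[1] != len(ALPHABET):
            raise ValueError("log_odds must have shape (length, 20)")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background frequencies must sum to 1")

    @property
    def length(self) -> int:
        return self.log_odds.shape[0]

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.log_odds.argmax(axis=1))

    def max_score(self) -> float:
        """Score of the best residue at every column (the consensus score)."""
        return float(self.log_odds.max(axis=1).sum())


def build_profile(
    member_sequences: Iterable[str],
    alpha: float = 1.0,
    background: np.ndarray | None = None,
) -> ProfileModel:
    """Build a PSSM from equal-length (column-aligned) family members.

    Column probabilities are ``(count + alpha * q) / (n + alpha)`` and
    log-odds are ``log2(p / q)``, floored at -20 bits where the count and
    pseudocount both vanish.
    """
    members = [s.upper() for s in member_sequences]
    if not members:
        raise ValueError("at least one member sequence required")
    lengths = {len(s) for s in members}
    if len(lengths) != 1:
        raise ValueError(
            "member sequences have unequal lengths; provide column-aligned input"
        )
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    q = (
        np.full(len(ALPHABET), 1.0 / len(ALPHABET))
        if background is None
        else np.asarray(background, dtype=float)
    )
    if not np.isclose(q.sum(), 1.0) or (q < 0).any():
        raise ValueError("background must be a probability distribution")

    length = lengths.pop()
    counts = np.zeros((length, len(ALPHABET)))
    for seq in members:
        for col, residue in enumerate(seq):
            if residue not in _AA_INDEX:
                raise ValueError(f"invalid residue {residue!r} in member sequence")
            counts[col, _AA_INDEX[residue]] += 1.0
    probs = (counts + alpha * q) / (len(members) + alpha)
    with np.errstate(divide="ignore"):
        log_odds = np.log2(probs / q)
    log_odds = np.maximum(log_odds, LOG_ODDS_FLOOR)
    return ProfileModel(log_odds=log_odds, background=q, alpha=alpha)


@dataclass(frozen=True)
class ScoreResult:
    seq_id: str
    score: float | None  # None when filtered
    filtered: bool


def _encode(seq: str) -> np.ndarray:
    idx = np.empty(len(seq), dtype=np.int64)
    for i, residue in enumerate(seq):
        if residue in _AA_INDEX:
            idx[i] = _AA_INDEX[residue]
        elif residue == "X":
            idx[i] = -1  # scores 0 at every column
        else:
            raise ValueError(f"invalid residue {residue!r} in query sequence")
    return idx


def score_sequence(
    profile: ProfileModel,
    seq: str,
    min_length: int = DEFAULT_MIN_LENGTH,
    seq_id: str = "query",
) -> ScoreResult:
    """Best ungapped placement score of the profile along a sequence.

    Sequences shorter than ``min_length`` residues are reported as
    filtered (fragment rule), not scored.  Placements slide the shorter of
    profile and sequence fully inside the longer; the score is the summed
    per-column log-odds of the best placement.  ``X`` residues score 0.
    """
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    idx = _encode(seq)
    if len(seq) < min_length:
        return ScoreResult(seq_id=seq_id, score=None, filtered=True)

    L, n = profile.length, len(seq)
    # per-(column, position) score matrix; X positions contribute 0
    M = profile.log_odds[:, np.clip(idx, 0, None)]
    M[:, idx < 0] = 0.0
    s0, s1 = M.strides
    if n >= L:
        # slide the profile along the sequence
        windows = np.lib.stride_tricks.as_strided(
            M, shape=(n - L + 1, L), strides=(s1, s0 + s1), writeable=False
        )
    else:
        # sequence shorter than profile: slide it inside the profile
        windows = np.lib.stride_tricks.as_strided(
            M, shape=(L - n + 1, n), strides=(s0, s0 + s1), writeable=False
        )
    return ScoreResult(seq_id=seq_id, score=float(windows.sum(axis=1).max()), filtered=False)


def score_all_placements(profile: ProfileModel, seq: str) -> np.ndarray:
    """Scores of every ungapped placement (no length filter); test hook."""
    idx = _encode(seq.upper())
    L, n = profile.length, len(idx)
    M = profile.log_odds[:, np.clip(idx, 0, None)]
    M[:, idx < 0] = 0.0
    if n >= L:
        return np.array([M[np.arange(L), o + np.arange(L)].sum() for o in range(n - L + 1)])
    return np.array([M[o + np.arange(n), np.arange(n)].sum() for o in range(L - n + 1)])


@dataclass
class CalibrationResult:
    """Adjacency-calibrated score threshold.

    ``excluded_genomes`` lists the genomes lacking peroxidase adjacency
    (the ones the threshold is built to exclude); ``collateral_exclusions``
    lists adjacent genomes that nevertheless fall below the threshold.
    """

    threshold: float
    delta: float
    excluded_genomes: list[str] = field(default_factory=list)
    collateral_exclusions: list[str] = field(default_factory=list)


def calibrate_threshold(
    genome_scores: Mapping[str, float],
    adjacency: Mapping[str, bool],
    delta: float = 1.0,
) -> CalibrationResult:
    """Set the hit threshold just above every non-adjacent genome's score.

    ``adjacency`` flags genomes whose best marker hit sits in a
    peroxidase-adjacent (idr-like) neighborhood.  The threshold is
    ``max(score over non-adjacent genomes) + delta``; with no non-adjacent
    genome it degenerates to the minimum adjacent score.  Adjacent genomes
    scoring below the threshold are reported as collateral exclusions.
    """
    if set(genome_scores) != set(adjacency):
        raise ValueError("genome_scores and adjacency must cover the same genomes")
    adjacent = sorted(g for g, flag in adjacency.items() if flag)
    non_adjacent = sorted(g for g, flag in adjacency.items() if not flag)
    if not adjacent:
        raise ValueError("calibration undefined: no genome with peroxidase adjacency")
    if non_adjacent:
        threshold = max(genome_scores[g] for g in non_adjacent) + delta
    else:
        threshold = min(genome_scores[g] for g in adjacent)
    collateral = [g for g in adjacent if genome_scores[g] < threshold]
    return CalibrationResult(
        threshold=threshold,
        delta=delta,
        excluded_genomes=non_adjacent,
        collateral_exclusions=collateral,
    )
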