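"""Marker search of sample ORF catalogs and TPM-based abundance summaries.

Each metagenome sample contributes a catalog of open reading frames with
per-ORF read counts.  The calibrated marker profile is run over every
catalog; per-ORF abundances are normalized to transcripts-per-million
(TPM) over the WHOLE catalog (the standard definition, so each sample's
TPM sums to 1e6), and the per-sample cumulative marker TPM plus hit counts
are aggregated by station and depth zone.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profile import DEFAULT_MIN_LENGTH, ProfileModel, score_sequence


@dataclass(frozen=True)
class OrfRecord:
    """One ORF in a sample catalog: nucleotide length plus read count."""

    sample_id: str
    orf_id: str
    length_bp: int
    read_count: int
    protein: str

    def __post_init__(self) -> None:
        if self.length_bp < 3:
            raise ValueError(f"ORF {self.orf_id}: length_bp must be >= 3")
        if self.read_count < 0:
            raise ValueError(f"ORF {self.orf_id}: read_count must be >= 0")


@dataclass(frozen=True)
class MarkerHit:
    sample_id: str
    orf_id: str
    score: float


@dataclass(frozen=True)
class SampleSummary:
    sample_id: str
    station: str
    depth: float
    zone: str
    n_marker_hits: int
    cumulative_marker_tpm: float

    def __post_init__(self) -> None:
        if self.n_marker_hits < 0 or self.cumulative_marker_tpm < 0:
            raise ValueError("hit count and cumulative TPM must be >= 0")


def search_sample(
    profile: ProfileModel,
    orfs: Iterable[OrfRecord],
    threshold: float,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> list[MarkerHit]:
    """ORFs passing the fragment filter and scoring at or above threshold."""
    hits: list[MarkerHit] = []
    for orf in orfs:
        result = score_sequence(profile, orf.protein, min_length=min_length, seq_id=orf.orf_id)
        if not result.filtered and result.score is not None and result.score >= threshold:
            hits.append(MarkerHit(sample_id=orf.sample_id, orf_id=orf.orf_id, score=result.score))
    return hits


def compute_tpm(
    read_counts: Sequence[int] | np.ndarray,
    lengths_bp: Sequence[int] | np.ndarray,
) -> np.ndarray:
    """Transcripts-per-million from raw counts and feature lengths.

    ``rate_i = count_i / (length_i / 1000)``; TPM scales rates so they sum
    to 1e6.  Raises if every count is zero (the normalization is undefined).
    """
    counts = np.asarray(read_counts, dtype=float)
    lengths = np.asarray(lengths_bp, dtype=float)
    if counts.shape != lengths.shape or counts.ndim != 1:
        raise ValueError("read_counts and lengths_bp must be 1-D and equal length")
    if (lengths <= 0).any():
        raise ValueError("lengths must be positive")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    rates = counts / (lengths / 1000.0)
    total = rates.sum()
    if total == 0:
        raise ValueError("all read counts are zero; TPM undefined")
    return rates / total * 1e6


def sample_tpm_table(orfs: Sequence[OrfRecord]) -> pd.Series:
    """Per-ORF TPM over one sample's full catalog, indexed by orf id."""
    if not orfs:
        raise ValueError("empty ORF catalog")
    tpm = compute_tpm([o.read_count for o in orfs], [o.length_bp for o in orfs])
    return pd.Series(tpm, index=[o.orf_id for o in orfs], name="tpm")


@dataclass
class SurveySummary:
    samples: list[SampleSummary]
    zone_fractions: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": s.sample_id,
                    "station": s.station,
                    "depth": s.depth,
                    "zone": s.zone,
                    "n_hits": s.n_marker_hits,
                    "cumulative_tpm": s.cumulative_marker_tpm,
                }
                for s in self.samples
            ]
        )


def summarize(
    hits: Iterable[MarkerHit],
    sample_orfs: Mapping[str, Sequence[OrfRecord]],
    sample_metadata: Mapping[str, Mapping[str, object]],
) -> SurveySummary:
    """Per-sample hit counts and cumulative marker TPM, plus zone fractions.

    ``sample_metadata`` maps sample ids to dicts with ``station``,
    ``depth`` and ``zone`` keys.  TPM is computed over each sample's full
    ORF catalog (denominator = all ORFs, not just hits); the cumulative
    marker TPM is the sum over that sample's hits.  Zone fractions are
    hits-in-zone over total hits (empty when there are no hits).
    """
    hits = list(hits)
    unknown = {h.sample_id for h in hits} - set(sample_orfs)
    if unknown:
        raise ValueError(f"hits reference unknown samples: {sorted(unknown)}")
    missing_meta = set(sample_orfs) - set(sample_metadata)
    if missing_meta:
        raise ValueError(f"samples missing metadata: {sorted(missing_meta)}")

    hits_by_sample: dict[str, list[MarkerHit]] = {sid: [] for sid in sample_orfs}
    for h in hits:
        hits_by_sample[h.sample_id].append(h)

    summaries: list[SampleSummary] = []
    zone_hits: dict[str, int] = {}
    for sample_id in sorted(sample_orfs):
        meta = sample_metadata[sample_id]
        sample_hits = hits_by_sample[sample_id]
        cumulative = 0.0
        if sample_hits:
            tpm = sample_tpm_table(sample_orfs[sample_id])
            cumulative = float(tpm.loc[[h.orf_id for h in sample_hits]].sum())
            zone = str(meta["zone"])
            zone_hits[zone] = zone_hits.get(zone, 0) + len(sample_hits)
        summaries.append(
            SampleSummary(
                sample_id=sample_id,
                station=str(meta["station"]),
                depth=float(meta["depth"]),  # type: ignore[arg-type]
                zone=str(meta["zone"]),
                n_marker_hits=len(sample_hits),
                cumulative_marker_tpm=cumulative,
            )
        )
    total_hits = sum(zone_hits.values())
    zone_fractions = (
        {zone: count / total_hits for zone, count in sorted(zone_hits.items())}
        if total_hits
        else {}
    )
    return SurveySummary(samples=summaries, zone_fractions=zone_fractions)
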