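"""All-vs-all local alignment, sequence-similarity network, greedy set cover.

Protein subfamilies are defined in three steps: exact Smith-Waterman local
alignment of every pair, an edge in the similarity network wherever the
expect-style significance and bidirectional coverage thresholds are met
(defaults 1e-3 and 0.5), and a greedy set-cover pass over the network that
repeatedly emits the node covering the most uncovered proteins together
with its uncovered neighbors.  The subfamilies partition the protein set
and are the unit of all downstream presence/absence comparison.

Significance is a Karlin-Altschul expect value computed from the gapped
BLOSUM62 bit score against the total residue count of the protein set, so
the 1e-3 cutoff behaves like a sequence-search E-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

# Gapped Karlin-Altschul parameters for BLOSUM62, gap open 11 / extend 1.
_KA_LAMBDA = 0.267
_KA_K = 0.041

_DEFAULT_MATRIX = "BLOSUM62"
_DEFAULT_GAP_OPEN = 11.0
_DEFAULT_GAP_EXTEND = 1.0

_VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYBZX*")


@dataclass(frozen=True)
class SimilarityHit:
    """One pairwise local-alignment result."""

    query_id: str
    target_id: str
    alignment_score: float
    percent_identity: float
    query_coverage: float
    target_coverage: float
    significance: float

    def __post_init__(self) -> None:
        for name in ("percent_identity", "query_coverage", "target_coverage"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0 + 1e-12):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.significance < 0:
            raise ValueError("significance must be >= 0")


@dataclass(frozen=True)
class Subfamily:
    subfamily_id: str
    representative_id: str
    member_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be a member")


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def _check_sequence(seq: str, label: str) -> None:
    if not seq:
        raise ValueError(f"{label} sequence is empty")
    bad = set(seq) - _VALID_RESIDUES
    if bad:
        raise ValueError(f"{label} sequence contains invalid characters {sorted(bad)}")


def expect_value(score: float, query_length: int, search_space: int) -> float:
    """Karlin-Altschul expect value for a raw gapped local-alignment score.

    ``search_space`` is the residue count of the effective database (for a
    single pair, the other sequence; for a network build, the whole set).
    """
    return _KA_K * query_length * search_space * math.exp(-_KA_LAMBDA * score)


def align_pair(
    a: str,
    b: str,
    matrix: str = _DEFAULT_MATRIX,
    gap_open: float = _DEFAULT_GAP_OPEN,
    gap_extend: float = _DEFAULT_GAP_EXTEND,
    query_id: str = "query",
    target_id: str = "target",
    search_space: int | None = None,
    _aligner: Align.PairwiseAligner | None = None,
) -> SimilarityHit:
    """Smith-Waterman local alignment of one protein pair.

    Identity is the match fraction over all alignment columns (gaps
    included); coverage is the aligned span divided by each sequence's
    length.  The hit is symmetric up to the query/target swap.
    """
    _check_sequence(a, "query")
    _check_sequence(b, "target")
    aligner = _aligner or _make_aligner(matrix, gap_open, gap_extend)
    alignments = aligner.align(a, b)
    if len(alignments) == 0 or alignments.score <= 0:
        return SimilarityHit(query_id, target_id, 0.0, 0.0, 0.0, 0.0, math.inf)
    aln = alignments[0]
    counts = aln.counts()  # gaps, identities, mismatches
    n_columns = counts.gaps + counts.identities + counts.mismatches
    identity = counts.identities / n_columns if n_columns else 0.0
    qa, ta = aln.aligned  # aligned segment blocks in each sequence
    q_span = qa[-1][1] - qa[0][0]
    t_span = ta[-1][1] - ta[0][0]
    space = search_space if search_space is not None else len(b)
    return SimilarityHit(
        query_id=query_id,
        target_id=target_id,
        alignment_score=float(aln.score),
        percent_identity=identity,
        query_coverage=q_span / len(a),
        target_coverage=t_span / len(b),
        significance=expect_value(aln.score, len(a), space),
    )


def build_network(
    proteins: dict[str, str],
    max_significance: float = 1e-3,
    min_coverage: float = 0.5,
    matrix: str = _DEFAULT_MATRIX,
    gap_open: float = _DEFAULT_GAP_OPEN,
    gap_extend: float = _DEFAULT_GAP_EXTEND,
) -> nx.Graph:
    """All-vs-all similarity network over a protein set.

    An undirected edge is present iff the pair's expect value is at most
    ``max_significance`` and BOTH coverages are at least ``min_coverage``
    (bidirectional coverage, the stricter of the two common dialects).
    Node order and edges are deterministic for fixed inputs.

    Pairs are screened with a score-only alignment pass first; the full
    traceback (needed only for coverage and identity) runs for pairs whose
    score alone clears the significance cutoff.
    """
    if not proteins:
        raise ValueError("at least one protein required")
    for pid, seq in proteins.items():
        _check_sequence(seq, pid)
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    ids = sorted(proteins)
    total_residues = sum(len(s) for s in proteins.values())

    ssn = nx.Graph()
    for pid in ids:
        ssn.add_node(pid, length=len(proteins[pid]))

    for i, qid in enumerate(ids):
        qseq = proteins[qid]
        # minimum raw score that can reach the significance cutoff
        min_score = (
            math.log(_KA_K * len(qseq) * total_residues / max_significance) / _KA_LAMBDA
        )
        for tid in ids[i + 1 :]:
            tseq = proteins[tid]
            if aligner.score(qseq, tseq) < min_score:
                continue
            hit = align_pair(
                qseq,
                tseq,
                query_id=qid,
                target_id=tid,
                search_space=total_residues,
                _aligner=aligner,
            )
            if (
                hit.significance <= max_significance
                and hit.query_coverage >= min_coverage
                and hit.target_coverage >= min_coverage
            ):
                ssn.add_edge(qid, tid, hit=hit)
    return ssn


def set_cover_cluster(ssn: nx.Graph) -> list[Subfamily]:
    """Greedy set-cover clustering of a similarity network.

    Repeatedly selects the uncovered node whose closed neighborhood
    contains the most uncovered nodes (ties broken by lexicographically
    smallest node id), emits that node as representative with its
    uncovered neighbors as members, and marks them covered.  The result
    partitions the node set.
    """
    uncovered = set(ssn.nodes)
    adjacency = {n: set(ssn.neighbors(n)) for n in ssn.nodes}
    subfamilies: list[Subfamily] = []
    while uncovered:
        best_id: str | None = None
        best_size = -1
        for node in sorted(uncovered):
            size = 1 + len(adjacency[node] & uncovered)
            if size > best_size:
                best_id, best_size = node, size
        assert best_id is not None
        members = frozenset({best_id} | (adjacency[best_id] & uncovered))
        subfamilies.append(
            Subfamily(
                subfamily_id=f"SF{len(subfamilies):05d}",
                representative_id=best_id,
                member_ids=members,
            )
        )
        uncovered -= members
    return subfamilies


def cluster_proteins(
    proteins: dict[str, str],
    max_significance: float = 1e-3,
    min_coverage: float = 0.5,
) -> tuple[nx.Graph, list[Subfamily]]:
    """Convenience wrapper: network construction followed by set cover."""
    ssn = build_network(proteins, max_significance=max_significance, min_coverage=min_coverage)
    return ssn, set_cover_cluster(ssn)
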