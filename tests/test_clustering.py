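"""Alignment, network and set-cover behaviour against independent oracles."""

import random

import networkx as nx
import pytest
from Bio.Align import substitution_matrices

from idrisle.clustering import (
    Subfamily,
    align_pair,
    build_network,
    set_cover_cluster,
)
from idrisle.synthetic import generate_protein_family

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gotoh_local_score(a: str, b: str, open_cost: float = 11.0, extend_cost: float = 1.0) -> float:
    """Brute-force affine-gap Smith-Waterman score oracle.

    A gap of length k costs open + (k-1) * extend (the first gap position
    pays the opening penalty), matching the aligner configuration.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - open_cost, E[i][j - 1] - extend_cost)
            F[i][j] = max(H[i - 1][j] - open_cost, F[i - 1][j] - extend_cost)
            sub = H[i - 1][j - 1] + BLOSUM62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestAlignPair:
    def test_self_alignment_full_identity_and_coverage(self):
        hit = align_pair("PEPTIDE", "PEPTIDE")
        assert hit.percent_identity == 1.0
        assert hit.query_coverage == 1.0 and hit.target_coverage == 1.0

    def test_score_symmetric_under_swap(self):
        a, b = "ACDEFGHIKLMNP", "ACDEFGWIKLMNP"
        assert align_pair(a, b).alignment_score == align_pair(b, a).alignment_score

    @pytest.mark.parametrize("seed", range(8))
    def test_score_matches_dp_oracle_on_short_pairs(self, seed):
        rng = random.Random(seed)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        a = "".join(rng.choice(aa) for _ in range(rng.randint(5, 10)))
        b = "".join(rng.choice(aa) for _ in range(rng.randint(5, 10)))
        hit = align_pair(a, b)
        assert hit.alignment_score == pytest.approx(gotoh_local_score(a, b))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_pair("", "PEPTIDE")


class TestBuildNetwork:
    def test_single_protein_yields_single_node_no_edges(self):
        ssn = build_network({"p1": "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"})
        assert ssn.number_of_nodes() == 1 and ssn.number_of_edges() == 0

    def test_one_family_forms_complete_graph(self):
        fam = generate_protein_family(120, 5, 0.9, seed=1)
        ssn = build_network({f"m{i}": s for i, s in enumerate(fam)})
        assert ssn.number_of_edges() == 10  # C(5,2)

    def test_no_edges_between_family_and_random(self):
        fam = generate_protein_family(120, 3, 0.9, seed=1)
        rnd = generate_protein_family(120, 1, 1.0, seed=99)  # unrelated ancestor
        proteins = {f"m{i}": s for i, s in enumerate(fam)}
        proteins["r0"] = rnd[0]
        ssn = build_network(proteins)
        assert not any("r0" in edge for edge in ssn.edges)

    def test_raising_min_coverage_never_adds_edges(self):
        fam = generate_protein_family(100, 4, 0.8, seed=2)
        proteins = {f"m{i}": s for i, s in enumerate(fam)}
        loose = set(build_network(proteins, min_coverage=0.3).edges)
        strict = set(build_network(proteins, min_coverage=0.9).edges)
        assert strict <= loose


def greedy_cover_oracle(graph: nx.Graph) -> list[tuple[str, frozenset]]:
    """Direct simulation of the greedy rule, written independently:
    scan uncovered nodes in sorted order, keep the first with the largest
    closed uncovered neighborhood, emit and repeat."""
    uncovered = set(graph.nodes)
    out = []
    while uncovered:
        ranked = sorted(
            uncovered,
            key=lambda v: (-len(({v} | set(graph[v])) & uncovered), v),
        )
        rep = ranked[0]
        members = frozenset(({rep} | set(graph[rep])) & uncovered)
        out.append((rep, members))
        uncovered -= members
    return out


class TestSetCover:
    def test_star_collapses_to_one_subfamily(self):
        g = nx.Graph([("A", "B"), ("A", "C")])
        subs = set_cover_cluster(g)
        assert len(subs) == 1
        assert subs[0].representative_id == "A"
        assert subs[0].member_ids == frozenset("ABC")

    def test_edgeless_graph_gives_singletons(self):
        g = nx.Graph()
        g.add_nodes_from("ABC")
        subs = set_cover_cluster(g)
        assert len(subs) == 3
        assert all(len(s.member_ids) == 1 for s in subs)

    def test_two_components_with_tie_break(self):
        g = nx.Graph([("A", "B"), ("A", "C"), ("D", "E")])
        subs = set_cover_cluster(g)
        assert [s.representative_id for s in subs] == ["A", "D"]
        assert subs[1].member_ids == frozenset("DE")

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_direct_oracle_on_random_graphs(self, seed):
        rng = random.Random(seed)
        n = rng.randint(1, 10)
        g = nx.gnp_random_graph(n, rng.uniform(0.1, 0.7), seed=seed)
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
        ours = [(s.representative_id, s.member_ids) for s in set_cover_cluster(g)]
        assert ours == greedy_cover_oracle(g)

    @pytest.mark.parametrize("seed", range(10))
    def test_partition_property(self, seed):
        g = nx.gnp_random_graph(12, 0.3, seed=seed)
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
        subs = set_cover_cluster(g)
        all_members = [m for s in subs for m in s.member_ids]
        assert len(all_members) == len(set(all_members)) == g.number_of_nodes()

    def test_representative_must_be_member(self):
        with pytest.raises(ValueError):
            Subfamily("SF0", "X", frozenset({"A"}))


class TestDefaultGenomeSetClustering:
    def test_family_members_share_subfamily(self, genome_set, clustered):
        """Genes planted from one ancestral family cluster together."""
        by_family: dict[str, set[str]] = {}
        for gene_id, fam in genome_set.truth.gene_families.items():
            by_family.setdefault(fam, set()).add(clustered.subfamily_of[gene_id])
        n_coherent = sum(1 for subs in by_family.values() if len(subs) == 1)
        assert n_coherent / len(by_family) > 0.95
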