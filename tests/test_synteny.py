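"""Neighborhood extraction, frequency, and idr/aio classification."""

import pytest

from idrisle.genomes import GeneRecord, Genome
from idrisle.synteny import (
    AIO_LIKE,
    AMBIGUOUS,
    IDR_LIKE,
    classify_synteny,
    extract,
    neighborhood_frequency,
)
from idrisle.synthetic import IslandSpec


def make_genome(n_genes, genome_id="G", strand_of=None, family_of=None):
    genes = []
    for i in range(n_genes):
        genes.append(
            GeneRecord(
                gene_id=f"{genome_id}_g{i:03d}",
                contig_id=f"{genome_id}_c1",
                start=i * 1000,
                end=i * 1000 + 900,
                strand=(strand_of or (lambda _: "+"))(i),
                protein="M" * 50,
                family_id=(family_of or (lambda i: f"fam{i}"))(i),
            )
        )
    return Genome(genome_id=genome_id, genes=genes)


class TestExtract:
    def test_interior_focal_gets_full_window(self):
        genome = make_genome(30)
        nb = extract(genome, "G_g015", k=10)
        assert len(nb.genes) == 21
        assert not nb.truncated_upstream and not nb.truncated_downstream
        assert nb.focal_index == 10

    def test_focal_near_contig_start_truncates_upstream(self):
        genome = make_genome(30)
        nb = extract(genome, "G_g001", k=10)
        assert len(nb.genes) == 12
        assert nb.truncated_upstream and not nb.truncated_downstream

    def test_minus_strand_reverses_gene_order(self):
        genome = make_genome(5, strand_of=lambda i: "-" if i == 2 else "+")
        nb = extract(genome, "G_g002", k=10)
        assert [g.gene_id for g in nb.genes] == [
            "G_g004", "G_g003", "G_g002", "G_g001", "G_g000"
        ]
        # both sides hit the contig end inside k=10
        assert nb.truncated_upstream and nb.truncated_downstream

    def test_offsets_centre_on_focal(self):
        genome = make_genome(7)
        nb = extract(genome, "G_g003", k=2)
        assert nb.offsets() == [-2, -1, 0, 1, 2]

    def test_unknown_focal_gene_rejected(self):
        with pytest.raises(KeyError):
            extract(make_genome(5), "nope")


class TestNeighborhoodFrequency:
    def _nb(self, genome_id, families):
        genome = make_genome(len(families), genome_id, family_of=lambda i: families[i])
        return extract(genome, f"{genome_id}_g000", k=len(families))

    def test_half_and_full_frequency(self):
        nbs = [
            self._nb("g1", ["X", "core"]),
            self._nb("g2", ["Y", "core"]),
            self._nb("g3", ["X", "core"]),
            self._nb("g4", ["Z", "core"]),
        ]
        freq = neighborhood_frequency(nbs)
        assert freq["X"] == 0.5
        assert freq["core"] == 1.0

    def test_two_of_three_genomes(self):
        nbs = [
            self._nb("g1", ["X"]),
            self._nb("g2", ["W"]),
            self._nb("g3", ["X"]),
        ]
        assert neighborhood_frequency(nbs)["X"] == pytest.approx(2 / 3)

    def test_frequency_ignores_gene_order_and_copies(self):
        a = neighborhood_frequency([self._nb("g1", ["A", "B"]), self._nb("g2", ["B", "A"])])
        b = neighborhood_frequency([self._nb("g1", ["B", "A", "A"]), self._nb("g2", ["A", "B"])])
        assert a["A"] == b["A"] == 1.0

    def test_duplicate_genome_ids_rejected(self):
        nb = self._nb("g1", ["X"])
        with pytest.raises(ValueError):
            neighborhood_frequency([nb, nb])


class TestClassifySynteny:
    island = IslandSpec()

    def _nb(self, families):
        genome = make_genome(len(families), "G", family_of=lambda i: families[i])
        return extract(genome, "G_g000", k=len(families))

    def test_partner_plus_both_peroxidases_is_idr_like(self):
        nb = self._nb(["fam_marker", "fam_partner", "fam_perox1", "fam_perox2"])
        assert classify_synteny(nb, self.island) == IDR_LIKE

    def test_partner_without_peroxidases_is_aio_like(self):
        nb = self._nb(["fam_marker", "fam_partner", "bg1", "bg2"])
        assert classify_synteny(nb, self.island) == AIO_LIKE

    def test_single_peroxidase_is_ambiguous(self):
        nb = self._nb(["fam_marker", "fam_partner", "fam_perox1", "bg"])
        assert classify_synteny(nb, self.island) == AMBIGUOUS

    def test_missing_partner_is_ambiguous(self):
        nb = self._nb(["fam_marker", "bg", "fam_perox1", "fam_perox2"])
        assert classify_synteny(nb, self.island) == AMBIGUOUS

    def test_strict_window_excludes_distant_peroxidases(self):
        nb = self._nb(["fam_marker", "fam_partner", "bg", "bg2", "fam_perox1", "fam_perox2"])
        assert classify_synteny(nb, self.island) == IDR_LIKE
        assert classify_synteny(nb, self.island, max_offset=2) == AIO_LIKE


class TestPlantedNeighborhoods:
    def test_all_planted_neighborhoods_classified_correctly(self, genome_set, calibrated):
        """Precision = recall = 1.0 for idr-like vs aio-like on the
        default synthetic set."""
        truth = genome_set.truth
        for nb in calibrated.neighborhoods:
            expected = IDR_LIKE if nb.genome_id in truth.ingroup_ids else AIO_LIKE
            got = classify_synteny(
                nb,
                partner_label=calibrated.partner_label,
                peroxidase_labels=calibrated.peroxidase_labels,
            )
            assert got == expected

    def test_island_subfamilies_fully_conserved_in_ingroup(
        self, genome_set, calibrated, island_subfamilies
    ):
        ingroup = set(genome_set.truth.ingroup_ids)
        nbs = [nb for nb in calibrated.neighborhoods if nb.genome_id in ingroup]
        assert len(nbs) == len(ingroup)
        freq = neighborhood_frequency(nbs)
        for sf_id in island_subfamilies.values():
            assert freq[sf_id] == 1.0
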