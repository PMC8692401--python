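"""Generator behaviour: identity control, planted structure, determinism."""

import numpy as np
import pytest

from idrisle.synthetic import (
    AMINO_ACIDS,
    ENV_VARIABLES,
    DecoySpec,
    IslandSpec,
    NicheModel,
    SimulationConfig,
    generate_genome_set,
    generate_metagenome,
    generate_protein_family,
    pairwise_identity,
)


class TestProteinFamily:
    def test_single_member_is_unmutated_ancestor(self):
        fam = generate_protein_family(100, 1, 0.9, seed=1)
        assert len(fam) == 1 and len(fam[0]) == 100

    def test_pairwise_identity_near_target(self):
        fam = generate_protein_family(100, 5, 0.90, seed=1)
        identities = [
            pairwise_identity(a, b) for i, a in enumerate(fam) for b in fam[i + 1 :]
        ]
        assert all(0.85 <= x <= 0.95 for x in identities)

    def test_identity_one_gives_identical_members(self):
        fam = generate_protein_family(100, 3, 1.0, seed=7)
        assert len(set(fam)) == 1

    @pytest.mark.parametrize("target", [0.55, 0.7, 0.9])
    def test_alphabet_and_length_preserved(self, target):
        fam = generate_protein_family(60, 4, target, seed=3)
        for seq in fam:
            assert len(seq) == 60
            assert set(seq) <= set(AMINO_ACIDS)

    def test_invalid_identity_rejected(self):
        with pytest.raises(ValueError):
            generate_protein_family(100, 3, 0.0, seed=1)


class TestGenomeSet:
    def test_island_planted_contiguously_in_order(self, genome_set, island_spec):
        for gid in genome_set.truth.ingroup_ids:
            genome = genome_set.by_id(gid)
            ordered = genome.genes_on_contig(genome.contigs()[0])
            island_genes = [g for g in ordered if g.family_id in island_spec.family_ids]
            assert len(island_genes) == 4
            strands = {g.strand for g in island_genes}
            assert len(strands) == 1  # one strand
            positions = [ordered.index(g) for g in island_genes]
            assert positions == list(range(positions[0], positions[0] + 4))
            families = [g.family_id for g in island_genes]
            if strands == {"-"}:
                families = families[::-1]
            assert tuple(families) == island_spec.gene_order

    def test_exactly_island_families_ingroup_unique(self, island_spec):
        """By construction, the only families in every in-group genome and
        no out-group genome are the four island families."""
        gs = generate_genome_set(
            SimulationConfig(seed=42, n_decoy_genomes=0), IslandSpec(), DecoySpec()
        )
        occupancy: dict[str, set[str]] = {}
        for genome in gs.genomes:
            for gene in genome.genes:
                occupancy.setdefault(gene.family_id, set()).add(genome.genome_id)
        ingroup, outgroup = set(gs.truth.ingroup_ids), set(gs.truth.outgroup_ids)
        unique = {
            fam
            for fam, genomes in occupancy.items()
            if ingroup <= genomes and not (genomes & outgroup)
        }
        assert unique == set(island_spec.family_ids)

    def test_outgroup_shares_background_with_ingroup(self, genome_set):
        fams = {
            gid: {g.family_id for g in genome_set.by_id(gid).genes}
            for gid in genome_set.truth.ingroup_ids + genome_set.truth.outgroup_ids
        }
        in0 = fams[genome_set.truth.ingroup_ids[0]]
        out0 = fams[genome_set.truth.outgroup_ids[0]]
        assert len(in0 & out0) > 20  # substantial overlap

    def test_decoy_has_marker_like_but_no_peroxidases(self, genome_set, island_spec):
        for gid in genome_set.truth.decoy_ids:
            fams = {g.family_id for g in genome_set.by_id(gid).genes}
            assert "fam_marker_like" in fams
            assert island_spec.partner_family_id in fams
            assert not (fams & set(island_spec.peroxidase_family_ids))

    def test_seed_determinism(self, default_config, island_spec):
        a = generate_genome_set(default_config, island_spec, DecoySpec())
        b = generate_genome_set(default_config, island_spec, DecoySpec())
        assert [g.genome_id for g in a.genomes] == [g.genome_id for g in b.genomes]
        for ga, gb in zip(a.genomes, b.genomes):
            assert ga.genes == gb.genes

    def test_small_genome_budget_rejected(self):
        with pytest.raises(ValueError):
            generate_genome_set(SimulationConfig(seed=1, genes_per_genome=5))


class TestMetagenome:
    def test_no_missing_cells_when_rate_zero(self):
        config = SimulationConfig(seed=5, n_samples=10, orfs_per_sample=20)
        sim = generate_metagenome(config, NicheModel(missing_rate=0.0))
        assert not sim.env.isna().any().any()
        assert sim.truth.masked_cells == {}

    def test_env_has_exactly_ten_canonical_columns(self, metagenome):
        assert tuple(metagenome.env.columns) == ENV_VARIABLES

    def test_marker_positive_samples_carry_long_marker_orf(self, metagenome):
        for sample in metagenome.samples:
            if metagenome.truth.marker_positive[sample.sample_id]:
                ids = set(metagenome.truth.marker_orfs[sample.sample_id])
                assert ids
                marker_orfs = [o for o in sample.orfs if o.orf_id in ids]
                assert all(len(o.protein) >= 280 for o in marker_orfs)

    def test_seed_determinism_of_positive_fraction(self):
        config = SimulationConfig(seed=11, n_samples=40, orfs_per_sample=5)
        a = generate_metagenome(config)
        b = generate_metagenome(config)
        assert a.truth.marker_positive == b.truth.marker_positive
        assert a.env.equals(b.env)

    def test_positive_samples_have_lower_oxygen(self):
        """Monte-Carlo check of the planted niche at generator defaults."""
        config = SimulationConfig(seed=42, n_samples=200, orfs_per_sample=5)
        sim = generate_metagenome(config)
        oxygen = "Mean_Oxygen (umol/kg)"
        values = {True: [], False: []}
        for sid, present in sim.truth.marker_positive.items():
            true_val = sim.truth.masked_cells.get((sid, oxygen), sim.env.at[sid, oxygen])
            values[present].append(true_val)
        assert values[True] and values[False]
        assert np.mean(values[True]) < np.mean(values[False])

    def test_masked_cells_recorded_with_true_values(self):
        config = SimulationConfig(seed=9, n_samples=30, orfs_per_sample=5)
        sim = generate_metagenome(config, NicheModel(missing_rate=0.2))
        assert sim.truth.masked_cells
        for (sid, var), value in sim.truth.masked_cells.items():
            assert np.isnan(sim.env.at[sid, var])
            assert np.isfinite(value)

    def test_invalid_missing_rate_rejected(self):
        with pytest.raises(ValueError):
            NicheModel(missing_rate=1.0)
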