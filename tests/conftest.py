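"""Session fixtures: one default simulated study, analysed once and shared.

The expensive stages (all-vs-all alignment of the default genome set) run
once per session; every test that needs the default study conditions
reuses these objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from idrisle import clustering, compare, profile as profmod, survey, synteny
from idrisle.synthetic import (
    DecoySpec,
    IslandSpec,
    NicheModel,
    SimulationConfig,
    generate_genome_set,
    generate_metagenome,
)


@pytest.fixture(scope="session")
def island_spec() -> IslandSpec:
    return IslandSpec()


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=42)


@pytest.fixture(scope="session")
def genome_set(default_config, island_spec):
    return generate_genome_set(default_config, island_spec, DecoySpec())


@dataclass
class Clustered:
    proteins: dict
    gene_to_genome: dict
    ssn: object
    subfamilies: list
    subfamily_of: dict  # gene_id -> subfamily_id
    matrix: object  # presence/absence DataFrame


@pytest.fixture(scope="session")
def clustered(genome_set) -> Clustered:
    proteins: dict[str, str] = {}
    gene_to_genome: dict[str, str] = {}
    for genome in genome_set.genomes:
        for gene in genome.genes:
            proteins[gene.gene_id] = gene.protein
            gene_to_genome[gene.gene_id] = genome.genome_id
    ssn, subfamilies = clustering.cluster_proteins(proteins)
    subfamily_of = {m: sf.subfamily_id for sf in subfamilies for m in sf.member_ids}
    matrix = compare.build_matrix(subfamilies, gene_to_genome)
    return Clustered(
        proteins=proteins,
        gene_to_genome=gene_to_genome,
        ssn=ssn,
        subfamilies=subfamilies,
        subfamily_of=subfamily_of,
        matrix=matrix,
    )


@pytest.fixture(scope="session")
def island_subfamilies(genome_set, clustered) -> dict[str, str]:
    """Planted island family id -> assigned subfamily id."""
    truth = genome_set.truth
    out: dict[str, str] = {}
    for gene_id, family in truth.gene_families.items():
        if family in truth.island_families and gene_id in clustered.subfamily_of:
            out.setdefault(family, clustered.subfamily_of[gene_id])
    return out


@dataclass
class CalibratedProfile:
    neighborhoods: list
    partner_label: str
    peroxidase_labels: tuple
    model: object
    genome_scores: dict
    adjacency: dict
    calibration: object


@pytest.fixture(scope="session")
def calibrated(genome_set, clustered, island_spec, island_subfamilies) -> CalibratedProfile:
    """Neighborhoods around every marker-subfamily gene, the marker PSSM
    built from the in-group copies, and the adjacency-calibrated threshold."""
    truth = genome_set.truth
    marker_sf = island_subfamilies[island_spec.marker_family_id]
    partner_label = island_subfamilies[island_spec.partner_family_id]
    peroxidase_labels = tuple(
        island_subfamilies[f] for f in island_spec.peroxidase_family_ids
    )
    neighborhoods = []
    for genome in genome_set.genomes:
        for gene in genome.genes:
            if clustered.subfamily_of[gene.gene_id] == marker_sf:
                neighborhoods.append(
                    synteny.extract(genome, gene.gene_id, k=10, labels=clustered.subfamily_of)
                )
    members = [
        nb.genes[nb.focal_index].protein
        for nb in neighborhoods
        if nb.genome_id in truth.ingroup_ids
    ]
    model = profmod.build_profile(members)
    genome_scores: dict[str, float] = {}
    adjacency: dict[str, bool] = {}
    for nb in neighborhoods:
        result = profmod.score_sequence(model, nb.genes[nb.focal_index].protein)
        assert not result.filtered
        if genome_scores.get(nb.genome_id, -1e18) < result.score:
            genome_scores[nb.genome_id] = result.score
            adjacency[nb.genome_id] = (
                synteny.classify_synteny(
                    nb, partner_label=partner_label, peroxidase_labels=peroxidase_labels
                )
                == synteny.IDR_LIKE
            )
    calibration = profmod.calibrate_threshold(genome_scores, adjacency)
    return CalibratedProfile(
        neighborhoods=neighborhoods,
        partner_label=partner_label,
        peroxidase_labels=peroxidase_labels,
        model=model,
        genome_scores=genome_scores,
        adjacency=adjacency,
        calibration=calibration,
    )


@pytest.fixture(scope="session")
def metagenome(default_config):
    return generate_metagenome(default_config, NicheModel())


@pytest.fixture(scope="session")
def survey_hits(calibrated, metagenome):
    hits = []
    for sample in metagenome.samples:
        hits.extend(
            survey.search_sample(
                calibrated.model, sample.orfs, threshold=calibrated.calibration.threshold
            )
        )
    return hits
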