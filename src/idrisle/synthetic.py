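"""Synthetic genomes, metagenome samples, and ocean metadata.

The generator emulates the statistical structure the island-discovery and
survey analyses assume, so the whole chain is testable without downloading
any deposited data:

* genome sets in which an ordered four-gene island (molybdopterin reductase
  marker + Rieske-like partner + two cytochrome c peroxidase-like genes) is
  planted contiguously in every in-group genome, absent from the out-group,
  and present as a peroxidase-free arsenite-oxidase-like decoy in decoy
  genomes;
* metagenome samples whose marker presence follows a logistic niche model
  driven by low oxygen and high nitrate, with ten named geochemical
  variables and missing-at-random metadata cells.

Evolution is substitution-only (no indels), which keeps family members
alignable column-to-column and lets the profile model be built without a
multiple-alignment engine.  Planted truth (island genomes, gene families,
marker-positive samples, masked cells) is returned alongside the data for
recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomes import GeneRecord, Genome
from .survey import OrfRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Canonical ocean-survey metadata column names, verbatim and ordered.
ENV_VARIABLES = (
    "Sampling depth (m)",
    "Mean_Temperature (deg C)",
    "Mean_Salinity (PSU)",
    "Mean_Oxygen (umol/kg)",
    "Mean_Nitrates (umol/L)",
    "NO_2 (umol/L)",
    "PO_4 (umol/L)",
    "SI (umol/L)",
    "NO_2NO_3 (umol/L)",
    "AMODIS:PAR8d, Einsteins/m-2/d-1",
)

ZONES = ("surface", "mixed", "DCM", "mesopelagic")


# ---------------------------------------------------------------------------
# Specifications


@dataclass(frozen=True)
class IslandSpec:
    """Layout of the planted iodate-reduction island.

    The default order mirrors the conserved idrABP1P2 synteny: catalytic
    marker, partner subunit, then the two peroxidase-like genes.
    """

    marker_family_id: str = "fam_marker"
    partner_family_id: str = "fam_partner"
    peroxidase_family_ids: tuple[str, str] = ("fam_perox1", "fam_perox2")
    gene_order: tuple[str, ...] = ()
    marker_length: int = 800
    accessory_length_range: tuple[int, int] = (150, 350)

    def __post_init__(self) -> None:
        if self.peroxidase_family_ids[0] == self.peroxidase_family_ids[1]:
            raise ValueError("peroxidase family ids must be distinct")
        order = self.gene_order or (
            self.marker_family_id,
            self.partner_family_id,
            *self.peroxidase_family_ids,
        )
        expected = {
            self.marker_family_id,
            self.partner_family_id,
            *self.peroxidase_family_ids,
        }
        if len(order) != 4 or set(order) != expected:
            raise ValueError("gene_order must contain each island family exactly once")
        object.__setattr__(self, "gene_order", tuple(order))

    @property
    def family_ids(self) -> tuple[str, ...]:
        return self.gene_order


@dataclass(frozen=True)
class DecoySpec:
    """Arsenite-oxidase-like decoy: marker homolog + partner, no peroxidases."""

    marker_like_identity: float = 0.55
    include_peroxidases: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.marker_like_identity <= 1.0):
            raise ValueError("marker_like_identity must be in [0, 1]")


@dataclass(frozen=True)
class NicheModel:
    """Geochemical niche of the marker-bearing populations.

    Marker presence per sample is Bernoulli with logistic probability
    ``sigmoid(intercept + coef_oxygen * z_oxygen + coef_nitrate * z_nitrate)``
    where z-scores standardize the drawn oxygen and nitrate values.  The
    remaining variables are drawn conditional on presence from the group
    means/SDs; oxygen and nitrate themselves are drawn first from a
    two-regime mixture (oxygen-depleted vs oxygenated water) so that the
    oxygen-nitrate anticorrelation of real ocean profiles is present in the
    table before presence is decided.
    """

    intercept: float = -1.0
    coef_oxygen: float = -2.5
    coef_nitrate: float = 1.0
    #: variable -> (absent-group mean, present-group mean)
    group_means: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    #: variable -> (absent-group SD, present-group SD)
    group_sds: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(_DEFAULT_SDS))
    low_oxygen_regime_prob: float = 0.35
    missing_rate: float = 0.10

    def __post_init__(self) -> None:
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0.0 < self.low_oxygen_regime_prob < 1.0):
            raise ValueError("low_oxygen_regime_prob must be in (0, 1)")
        for var in ENV_VARIABLES:
            if var not in self.group_means or var not in self.group_sds:
                raise ValueError(f"niche model missing variable {var!r}")
            if any(s <= 0 for s in self.group_sds[var]):
                raise ValueError(f"SDs must be positive for {var!r}")


# Group means/SDs (absent, present) chosen to echo published contrasts:
# marker-positive sites sit deeper, colder, oxygen-poor and nutrient-rich.
_DEFAULT_MEANS = {
    "Sampling depth (m)": (150.0, 460.0),
    "Mean_Temperature (deg C)": (18.0, 10.0),
    "Mean_Salinity (PSU)": (35.0, 34.8),
    "Mean_Oxygen (umol/kg)": (190.0, 65.0),
    "Mean_Nitrates (umol/L)": (10.0, 30.0),
    "NO_2 (umol/L)": (0.10, 0.25),
    "PO_4 (umol/L)": (0.8, 2.2),
    "SI (umol/L)": (12.0, 40.0),
    "NO_2NO_3 (umol/L)": (10.1, 30.2),
    "AMODIS:PAR8d, Einsteins/m-2/d-1": (25.0, 8.0),
}
_DEFAULT_SDS = {
    "Sampling depth (m)": (120.0, 180.0),
    "Mean_Temperature (deg C)": (5.0, 3.0),
    "Mean_Salinity (PSU)": (0.6, 0.6),
    "Mean_Oxygen (umol/kg)": (45.0, 35.0),
    "Mean_Nitrates (umol/L)": (5.0, 8.0),
    "NO_2 (umol/L)": (0.05, 0.12),
    "PO_4 (umol/L)": (0.35, 0.6),
    "SI (umol/L)": (7.0, 14.0),
    "NO_2NO_3 (umol/L)": (5.0, 8.0),
    "AMODIS:PAR8d, Einsteins/m-2/d-1": (12.0, 5.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Sizes and seed for one simulation; the seed fixes every draw."""

    seed: int = 42
    n_ingroup: int = 2
    n_outgroup: int = 2
    n_decoy_genomes: int = 1
    genes_per_genome: int = 60
    n_samples: int = 40
    orfs_per_sample: int = 300
    zone_probs: tuple[float, float, float, float] = (0.10, 0.10, 0.30, 0.50)

    def __post_init__(self) -> None:
        for name in ("genes_per_genome", "n_samples", "orfs_per_sample"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if min(self.n_ingroup, self.n_outgroup, self.n_decoy_genomes) < 0:
            raise ValueError("genome counts must be >= 0")
        if abs(sum(self.zone_probs) - 1.0) > 1e-9:
            raise ValueError("zone_probs must sum to 1")


# ---------------------------------------------------------------------------
# Protein families


_AA_BYTES = np.frombuffer(AMINO_ACIDS.encode("ascii"), dtype=np.uint8)


def _random_protein(length: int, rng: np.random.Generator) -> str:
    return bytes(_AA_BYTES[rng.integers(0, len(_AA_BYTES), size=length)]).decode("ascii")


def _mutate(seq: str, n_subst: int, rng: np.random.Generator) -> str:
    """Substitute exactly ``n_subst`` distinct positions to a different residue."""
    if n_subst == 0:
        return seq
    chars = list(seq)
    positions = rng.choice(len(chars), size=n_subst, replace=False)
    for pos in positions:
        alternatives = [a for a in AMINO_ACIDS if a != chars[pos]]
        chars[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def _divergence_for_pairwise_identity(target: float) -> float:
    """Per-member substitution fraction d so that two independently mutated
    copies of one ancestor have expected identity ``target``.

    A position keeps the ancestor residue with probability (1-d); positions
    mutated in both copies coincide with probability 1/19, giving expected
    identity 1 - 2d + (20/19) d^2.
    """
    a, b, c = 20.0 / 19.0, -2.0, 1.0 - target
    disc = b * b - 4 * a * c
    return (-b - math.sqrt(disc)) / (2 * a)


def _divergence_for_identity_to_ancestor(target: float) -> float:
    """Substitution fraction d so a single mutant has identity ``target``
    to the unmutated ancestor: identity = 1 - (18/19) d."""
    return (1.0 - target) * 19.0 / 18.0


def generate_protein_family(
    ancestor_length: int,
    n_members: int,
    target_identity: float,
    seed: int | np.random.Generator,
    ancestor: str | None = None,
) -> list[str]:
    """Simulate a protein family by substitution-only divergence.

    Each member is mutated independently from a common (random or supplied)
    ancestor at the fixed number of positions that makes the expected
    member-to-member identity equal ``target_identity``.  A single-member
    family is the unmutated ancestor.
    """
    if not (0.0 < target_identity <= 1.0):
        raise ValueError("target_identity must be in (0, 1]")
    if ancestor_length < 20:
        raise ValueError("ancestor_length must be >= 20")
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if ancestor is None:
        ancestor = _random_protein(ancestor_length, rng)
    elif len(ancestor) != ancestor_length:
        raise ValueError("ancestor length does not match ancestor_length")
    if n_members == 1:
        return [ancestor]
    d = _divergence_for_pairwise_identity(target_identity)
    k = int(round(d * ancestor_length))
    return [_mutate(ancestor, k, rng) for _ in range(n_members)]


def pairwise_identity(a: str, b: str) -> float:
    """Column-to-column identity of two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x == y for x, y in zip(a, b)) / len(a)


# ---------------------------------------------------------------------------
# Genome sets


@dataclass
class GenomeSetTruth:
    """Planted ground truth for one simulated genome set."""

    ingroup_ids: list[str]
    outgroup_ids: list[str]
    decoy_ids: list[str]
    island_families: tuple[str, ...]
    #: gene_id -> true family id, across all genomes
    gene_families: dict[str, str]
    #: genome_id -> gene id of the marker (or marker-like decoy) copy
    marker_genes: dict[str, str]


@dataclass
class GenomeSet:
    genomes: list[Genome]
    truth: GenomeSetTruth

    def by_id(self, genome_id: str) -> Genome:
        for g in self.genomes:
            if g.genome_id == genome_id:
                return g
        raise KeyError(genome_id)


#: identity targets used when diverging family members between genomes
_FAMILY_IDENTITY = 0.90
_BACKGROUND_INCLUSION = 0.70
_INTERGENIC_BP = 50


def generate_genome_set(
    config: SimulationConfig,
    island: IslandSpec | None = None,
    decoy: DecoySpec | None = None,
) -> GenomeSet:
    """Simulate in-group genomes carrying the island, out-group genomes
    without it, and decoy genomes carrying a peroxidase-free marker-like
    neighborhood.

    Background genes come from a shared family pool with per-genome
    inclusion probability 0.7, so in- and out-groups overlap substantially
    and the in-group-unique set is exactly the planted island.
    """
    island = island or IslandSpec()
    decoy = decoy or DecoySpec()
    island_size = len(island.family_ids)
    if config.genes_per_genome < island_size + 2:
        raise ValueError("genes_per_genome must be at least island size + 2")
    rng = np.random.default_rng(config.seed)

    n_total = config.n_ingroup + config.n_outgroup + config.n_decoy_genomes
    if n_total < 1:
        raise ValueError("at least one genome required")

    # Ancestors for island families.
    lo, hi = island.accessory_length_range
    ancestors: dict[str, str] = {}
    for fam in island.family_ids:
        length = island.marker_length if fam == island.marker_family_id else int(rng.integers(lo, hi + 1))
        ancestors[fam] = _random_protein(length, rng)

    # Shared background family pool (1.5x genes_per_genome ancestors).
    n_pool = int(math.ceil(config.genes_per_genome * 1.5))
    pool_ids = [f"fam_bg{i:04d}" for i in range(n_pool)]
    for fam in pool_ids:
        ancestors[fam] = _random_protein(int(rng.integers(lo, hi + 1)), rng)

    member_div = _divergence_for_pairwise_identity(_FAMILY_IDENTITY)

    def _family_copy(fam: str) -> str:
        anc = ancestors[fam]
        k = int(round(member_div * len(anc)))
        return _mutate(anc, k, rng)

    genome_roles = (
        [("ingroup", i) for i in range(config.n_ingroup)]
        + [("outgroup", i) for i in range(config.n_outgroup)]
        + [("decoy", i) for i in range(config.n_decoy_genomes)]
    )

    # Background occupancy matrix (pool families x genomes): each family in
    # each genome with prob 0.7, columns trimmed/filled to the per-genome
    # background budget, then repaired so no background family reproduces
    # the island's signature pattern (all in-group, no out-group) — the
    # in-group-unique set must be exactly the planted island.
    island_sizes = {"ingroup": island_size, "outgroup": 0, "decoy": 2 + (2 if decoy.include_peroxidases else 0)}
    budgets = [config.genes_per_genome - island_sizes[role] for role, _ in genome_roles]
    inclusion = rng.random((n_pool, len(genome_roles))) < _BACKGROUND_INCLUSION
    for gi, budget in enumerate(budgets):
        on = np.flatnonzero(inclusion[:, gi])
        off = np.flatnonzero(~inclusion[:, gi])
        if on.size > budget:
            drop = rng.choice(on, size=on.size - budget, replace=False)
            inclusion[drop, gi] = False
        elif on.size < budget:
            add = rng.choice(off, size=budget - on.size, replace=False)
            inclusion[add, gi] = True
    in_cols = [gi for gi, (role, _) in enumerate(genome_roles) if role == "ingroup"]
    out_cols = [gi for gi, (role, _) in enumerate(genome_roles) if role == "outgroup"]
    if in_cols and out_cols:
        for fi in range(n_pool):
            if inclusion[fi, in_cols].all() and not inclusion[fi, out_cols].any():
                # break the pattern: drop from one in-group genome and swap in
                # a family already present in the out-group (cannot become
                # in-group-unique), keeping the gene budget intact
                gi = in_cols[int(rng.integers(len(in_cols)))]
                inclusion[fi, gi] = False
                candidates = np.flatnonzero(
                    ~inclusion[:, gi] & inclusion[:, out_cols].any(axis=1)
                )
                if candidates.size:
                    inclusion[candidates[int(rng.integers(candidates.size))], gi] = True

    genomes: list[Genome] = []
    truth = GenomeSetTruth(
        ingroup_ids=[],
        outgroup_ids=[],
        decoy_ids=[],
        island_families=island.family_ids,
        gene_families={},
        marker_genes={},
    )

    decoy_marker_div = _divergence_for_identity_to_ancestor(decoy.marker_like_identity)

    for gi, (role, idx) in enumerate(genome_roles):
        genome_id = f"{role}_{idx:02d}"
        getattr(truth, f"{role}_ids").append(genome_id)

        chosen = [pool_ids[fi] for fi in np.flatnonzero(inclusion[:, gi])]
        rng.shuffle(chosen)

        # Build the ordered gene/family layout for the contig.
        layout: list[tuple[str, str]] = [(fam, _family_copy(fam)) for fam in chosen]
        island_strand = "+" if rng.random() < 0.5 else "-"
        if role == "ingroup":
            block = [(fam, _family_copy(fam)) for fam in island.gene_order]
            if island_strand == "-":
                block.reverse()  # keep gene_order in reading direction
            pos = int(rng.integers(0, len(layout) + 1))
            layout[pos:pos] = block
            island_families_here = set(island.gene_order)
        elif role == "decoy":
            marker_anc = ancestors[island.marker_family_id]
            k = int(round(decoy_marker_div * len(marker_anc)))
            marker_like = _mutate(marker_anc, k, rng)
            block = [
                ("fam_marker_like", marker_like),
                (island.partner_family_id, _family_copy(island.partner_family_id)),
            ]
            if decoy.include_peroxidases:
                block += [(fam, _family_copy(fam)) for fam in island.peroxidase_family_ids]
            if island_strand == "-":
                block.reverse()
            pos = int(rng.integers(0, len(layout) + 1))
            layout[pos:pos] = block
            island_families_here = {fam for fam, _ in block}
        else:
            island_families_here = set()

        # Lay genes on one contig with fixed intergenic spacing.
        genes: list[GeneRecord] = []
        cursor = 0
        contig = f"{genome_id}_c1"
        for j, (fam, protein) in enumerate(layout):
            gene_id = f"{genome_id}_g{j:04d}"
            length_bp = 3 * (len(protein) + 1)
            if fam in island_families_here:
                strand = island_strand
            else:
                strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    contig_id=contig,
                    start=cursor,
                    end=cursor + length_bp,
                    strand=strand,
                    protein=protein,
                    family_id=fam,
                )
            )
            truth.gene_families[gene_id] = fam
            if fam in (island.marker_family_id, "fam_marker_like"):
                truth.marker_genes[genome_id] = gene_id
            cursor += length_bp + _INTERGENIC_BP
        genomes.append(Genome(genome_id=genome_id, genes=genes))

    return GenomeSet(genomes=genomes, truth=truth)


# ---------------------------------------------------------------------------
# Metagenome samples + environmental metadata


@dataclass
class MetagenomeSample:
    sample_id: str
    station: str
    depth: float
    zone: str
    orfs: list[OrfRecord]


@dataclass
class MetagenomeTruth:
    """Planted truth for one simulated survey."""

    #: sample_id -> True if the sample carries >=1 marker-derived ORF
    marker_positive: dict[str, bool]
    #: sample_id -> ids of the marker-derived ORFs
    marker_orfs: dict[str, list[str]]
    #: (sample_id, variable) -> true value that was masked to NaN
    masked_cells: dict[tuple[str, str], float]


@dataclass
class MetagenomeSurvey:
    samples: list[MetagenomeSample]
    env: pd.DataFrame  # samples x ten variables, NaN where masked
    truth: MetagenomeTruth


_ZONE_DEPTH = {  # (low, high) metres, uniform draw
    "surface": (3.0, 10.0),
    "mixed": (20.0, 80.0),
    "DCM": (40.0, 180.0),
    "mesopelagic": (270.0, 800.0),
}
#: probability the water regime is oxygen-depleted, by zone
_ZONE_LOW_O2_PROB = {"surface": 0.05, "mixed": 0.10, "DCM": 0.35, "mesopelagic": 0.60}

_NB_DISPERSION = 5.0
_ORF_AA_RANGE = (100, 500)


def _negbinom(rng: np.random.Generator, mean: float) -> int:
    """Negative-binomial draw with fixed dispersion, mean ``mean``."""
    if mean <= 0:
        return 0
    p = _NB_DISPERSION / (_NB_DISPERSION + mean)
    return int(rng.negative_binomial(_NB_DISPERSION, p))


def generate_metagenome(
    config: SimulationConfig,
    niche: NicheModel | None = None,
    marker_sequences: list[str] | None = None,
) -> MetagenomeSurvey:
    """Simulate per-sample ORF catalogs and the ten-variable metadata table.

    Marker presence follows the niche logistic model on drawn oxygen and
    nitrate; positive samples receive 1-3 full-length marker-derived ORFs
    whose read counts scale with 1/oxygen, giving the cumulative-TPM vs
    oxygen signal the survey stage looks for.  Metadata cells are masked
    missing-at-random at ``niche.missing_rate``.
    """
    niche = niche or NicheModel()
    rng = np.random.default_rng(config.seed)
    if marker_sequences is None:
        marker_sequences = generate_protein_family(800, 4, _FAMILY_IDENTITY, rng)
    if any(len(s) < 280 for s in marker_sequences):
        raise ValueError("marker sequences must be >= 280 residues")

    zone_idx = rng.choice(len(ZONES), size=config.n_samples, p=config.zone_probs)
    ox_mu = niche.group_means["Mean_Oxygen (umol/kg)"]
    ox_sd = niche.group_sds["Mean_Oxygen (umol/kg)"]
    no3_mu = niche.group_means["Mean_Nitrates (umol/L)"]
    no3_sd = niche.group_sds["Mean_Nitrates (umol/L)"]
    # pooled standardization constants for the logistic link
    ox_center, ox_scale = (ox_mu[0] + ox_mu[1]) / 2, (ox_mu[0] - ox_mu[1]) / 2 + ox_sd[0]
    no3_center, no3_scale = (no3_mu[0] + no3_mu[1]) / 2, (no3_mu[1] - no3_mu[0]) / 2 + no3_sd[0]

    samples: list[MetagenomeSample] = []
    env_rows: list[dict[str, float]] = []
    truth = MetagenomeTruth(marker_positive={}, marker_orfs={}, masked_cells={})

    for i in range(config.n_samples):
        sample_id = f"S{i:04d}"
        zone = ZONES[zone_idx[i]]
        depth = float(rng.uniform(*_ZONE_DEPTH[zone]))

        # Water regime then oxygen/nitrate: anticorrelated by construction.
        low_o2 = rng.random() < _ZONE_LOW_O2_PROB[zone]
        regime = 1 if low_o2 else 0
        oxygen = max(1.0, float(rng.normal(ox_mu[regime], ox_sd[regime])))
        nitrate = max(0.0, float(rng.normal(no3_mu[regime], no3_sd[regime])))

        logit = (
            niche.intercept
            + niche.coef_oxygen * (oxygen - ox_center) / ox_scale
            + niche.coef_nitrate * (nitrate - no3_center) / no3_scale
        )
        present = bool(rng.random() < 1.0 / (1.0 + math.exp(-logit)))
        truth.marker_positive[sample_id] = present

        group = 1 if present else 0
        row: dict[str, float] = {}
        for var in ENV_VARIABLES:
            if var == "Mean_Oxygen (umol/kg)":
                row[var] = oxygen
            elif var == "Mean_Nitrates (umol/L)":
                row[var] = nitrate
            elif var == "Sampling depth (m)":
                row[var] = depth
            elif var == "NO_2NO_3 (umol/L)":
                no2 = max(
                    0.0,
                    float(
                        rng.normal(niche.group_means["NO_2 (umol/L)"][group], niche.group_sds["NO_2 (umol/L)"][group])
                    ),
                )
                row["NO_2 (umol/L)"] = no2
                row[var] = nitrate + no2
            elif var == "NO_2 (umol/L)":
                continue  # filled with NO_2NO_3 above
            else:
                mu = niche.group_means[var][group]
                sd = niche.group_sds[var][group]
                row[var] = float(rng.normal(mu, sd))
        env_rows.append(row)

        # Background ORFs.
        orfs: list[OrfRecord] = []
        n_aa = rng.integers(_ORF_AA_RANGE[0], _ORF_AA_RANGE[1] + 1, size=config.orfs_per_sample)
        abundances = rng.lognormal(mean=0.0, sigma=1.0, size=config.orfs_per_sample)
        for j in range(config.orfs_per_sample):
            protein = _random_protein(int(n_aa[j]), rng)
            length_bp = 3 * (len(protein) + 1)
            count = _negbinom(rng, length_bp * abundances[j] / 1000.0)
            orfs.append(
                OrfRecord(
                    sample_id=sample_id,
                    orf_id=f"{sample_id}_orf{j:05d}",
                    length_bp=length_bp,
                    read_count=count,
                    protein=protein,
                )
            )

        # Marker-derived ORFs in positive samples.
        truth.marker_orfs[sample_id] = []
        if present:
            n_marker = 1 + int(rng.poisson(0.8))
            marker_abundance = 150.0 / max(oxygen, 5.0)
            for m in range(n_marker):
                template = marker_sequences[int(rng.integers(len(marker_sequences)))]
                protein = _mutate(template, int(round(0.05 * len(template))), rng)
                length_bp = 3 * (len(protein) + 1)
                count = max(1, _negbinom(rng, length_bp * marker_abundance / 1000.0))
                orf_id = f"{sample_id}_marker{m:02d}"
                orfs.append(
                    OrfRecord(
                        sample_id=sample_id,
                        orf_id=orf_id,
                        length_bp=length_bp,
                        read_count=count,
                        protein=protein,
                    )
                )
                truth.marker_orfs[sample_id].append(orf_id)

        samples.append(
            MetagenomeSample(
                sample_id=sample_id,
                station=f"ST{i:04d}",
                depth=depth,
                zone=zone,
                orfs=orfs,
            )
        )

    env = pd.DataFrame(env_rows, index=[s.sample_id for s in samples])
    env = env[list(ENV_VARIABLES)]
    env.index.name = "sample_id"

    # MCAR masking, never masking a column down to <2 observed values.
    if niche.missing_rate > 0:
        mask = rng.random(env.shape) < niche.missing_rate
        for ci, var in enumerate(env.columns):
            col_mask = mask[:, ci]
            max_missing = env.shape[0] - 2
            if col_mask.sum() > max_missing:
                on = np.flatnonzero(col_mask)
                col_mask[on[max_missing:]] = False
            for ri in np.flatnonzero(col_mask):
                sample_id = env.index[ri]
                truth.masked_cells[(sample_id, var)] = float(env.iat[ri, ci])
                env.iat[ri, ci] = np.nan

    return MetagenomeSurvey(samples=samples, env=env, truth=truth)
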