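"""Presence/absence matrix over subfamilies and in-group-unique gene discovery.

The island that enables iodate respiration was found by asking which
protein subfamilies occur in every genome of the respiring in-group and in
no genome of the closely related non-respiring out-group.  This module
builds the boolean genome x subfamily occupancy matrix, evaluates that
shared-unique rule for arbitrary groupings, and partitions subfamilies
into Venn regions for 2-4 genomes.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import pandas as pd

from .clustering import Subfamily

#: A Venn partition maps a region (frozenset of genome ids) to the set of
#: subfamilies present in exactly those genomes.
VennPartition = dict[frozenset, set]


def build_matrix(
    subfamilies: Iterable[Subfamily],
    gene_to_genome: Mapping[str, str],
) -> pd.DataFrame:
    """Boolean presence/absence matrix (genomes x subfamilies).

    A cell is True iff at least one member of the subfamily is annotated
    in the genome (occupancy is boolean regardless of copy number).  Rows
    and columns are sorted for deterministic output.
    """
    subfamilies = list(subfamilies)
    for sf in subfamilies:
        for gene in sf.member_ids:
            if gene not in gene_to_genome:
                raise KeyError(f"gene {gene!r} in {sf.subfamily_id} maps to no genome")
    genome_ids = sorted(set(gene_to_genome.values()))
    subfamily_ids = sorted(sf.subfamily_id for sf in subfamilies)
    matrix = pd.DataFrame(False, index=genome_ids, columns=subfamily_ids, dtype=bool)
    for sf in subfamilies:
        for gene in sf.member_ids:
            matrix.loc[gene_to_genome[gene], sf.subfamily_id] = True
    matrix.index.name = "genome_id"
    matrix.columns.name = "subfamily_id"
    return matrix


def _check_groups(matrix: pd.DataFrame, ingroup: Iterable[str], outgroup: Iterable[str]) -> tuple[list, list]:
    ingroup, outgroup = list(ingroup), list(outgroup)
    if not ingroup or not outgroup:
        raise ValueError("ingroup and outgroup must both be nonempty")
    overlap = set(ingroup) & set(outgroup)
    if overlap:
        raise ValueError(f"ingroup and outgroup overlap: {sorted(overlap)}")
    missing = (set(ingroup) | set(outgroup)) - set(matrix.index)
    if missing:
        raise ValueError(f"genomes not in matrix: {sorted(missing)}")
    return ingroup, outgroup


def shared_unique(
    matrix: pd.DataFrame,
    ingroup: Iterable[str],
    outgroup: Iterable[str],
) -> set[str]:
    """Subfamilies present in ALL in-group genomes and NO out-group genome."""
    ingroup, outgroup = _check_groups(matrix, ingroup, outgroup)
    in_all = matrix.loc[ingroup].all(axis=0)
    in_none = ~matrix.loc[outgroup].any(axis=0)
    return set(matrix.columns[in_all & in_none])


def venn_counts(matrix: pd.DataFrame, genomes: Iterable[str]) -> VennPartition:
    """Partition subfamilies into Venn regions of 2-4 genomes.

    Each subfamily present in at least one listed genome is assigned to
    exactly the region (nonempty subset of the listed genomes) whose
    members all contain it and whose non-members all lack it.
    """
    genomes = list(genomes)
    if not (2 <= len(genomes) <= 4):
        raise ValueError("venn_counts supports between 2 and 4 genomes")
    if len(set(genomes)) != len(genomes):
        raise ValueError("duplicate genome ids")
    missing = set(genomes) - set(matrix.index)
    if missing:
        raise ValueError(f"genomes not in matrix: {sorted(missing)}")
    sub = matrix.loc[genomes]
    partition: VennPartition = {}
    for sf_id in matrix.columns:
        region = frozenset(g for g in genomes if sub.at[g, sf_id])
        if region:
            partition.setdefault(region, set()).add(sf_id)
    return partition


def region_counts(partition: VennPartition) -> dict[frozenset, int]:
    return {region: len(members) for region, members in partition.items()}


def shared_unique_report(
    matrix: pd.DataFrame,
    ingroup: Iterable[str],
    outgroup: Iterable[str],
    subfamilies: Iterable[Subfamily],
    gene_to_genome: Mapping[str, str],
) -> pd.DataFrame:
    """Long-form report of the shared-unique subfamilies: one row per
    member gene per in-group genome."""
    unique_ids = shared_unique(matrix, ingroup, outgroup)
    rows = []
    for sf in subfamilies:
        if sf.subfamily_id not in unique_ids:
            continue
        for gene in sorted(sf.member_ids):
            genome = gene_to_genome[gene]
            if genome in set(ingroup):
                rows.append(
                    {"subfamily_id": sf.subfamily_id, "genome_id": genome, "gene_id": gene}
                )
    return pd.DataFrame(rows, columns=["subfamily_id", "genome_id", "gene_id"]).sort_values(
        ["subfamily_id", "genome_id", "gene_id"], ignore_index=True
    )
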