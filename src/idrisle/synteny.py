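"""Gene-neighborhood extraction and idr-like vs aio-like classification.

Iodate-reductase loci are distinguished from arsenite-oxidase loci by
their neighborhoods: a true iodate-reduction island carries the partner
subunit and both cytochrome c peroxidase families near the catalytic
marker, while arsenite-oxidase-like loci carry the partner but no
peroxidases.  Neighborhoods are the up-to-ten genes on either side of the
focal locus on its contig, orientation-normalized so the focal strand
reads left to right.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass

from .genomes import GeneRecord, Genome
from .synthetic import IslandSpec

IDR_LIKE = "idr_like"
AIO_LIKE = "aio_like"
AMBIGUOUS = "ambiguous"


@dataclass
class Neighborhood:
    """Up to 10+1+10 genes around a focal locus, reading-direction ordered."""

    genome_id: str
    focal_gene_id: str
    genes: list[GeneRecord]
    labels: list[str | None]  # subfamily or family label per gene
    truncated_upstream: bool
    truncated_downstream: bool

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.labels):
            raise ValueError("labels must parallel genes")
        n_focal = sum(g.gene_id == self.focal_gene_id for g in self.genes)
        if n_focal != 1:
            raise ValueError("focal gene must appear exactly once")

    @property
    def focal_index(self) -> int:
        for i, g in enumerate(self.genes):
            if g.gene_id == self.focal_gene_id:
                return i
        raise AssertionError("unreachable")

    def offsets(self) -> list[int]:
        """Signed gene offsets relative to the focal locus (0 = focal)."""
        f = self.focal_index
        return [i - f for i in range(len(self.genes))]


def extract(
    genome: Genome,
    focal_gene_id: str,
    k: int = 10,
    labels: Mapping[str, str] | None = None,
) -> Neighborhood:
    """Extract up to ``k`` genes on each side of the focal gene.

    Genes come from the focal contig only, never wrapping; truncation
    flags are set when the contig boundary arrives before ``k`` genes.
    If the focal gene lies on the minus strand the list is reversed so
    that upstream/downstream follow the focal gene's reading direction.
    ``labels`` maps gene ids to subfamily labels; by default each gene's
    own ``family_id`` is used.
    """
    focal = genome.get_gene(focal_gene_id)
    ordered = genome.genes_on_contig(focal.contig_id)
    idx = next(i for i, g in enumerate(ordered) if g.gene_id == focal_gene_id)
    lo = max(0, idx - k)
    hi = min(len(ordered), idx + k + 1)
    window = ordered[lo:hi]
    left_truncated = idx - k < 0
    right_truncated = idx + k + 1 > len(ordered)
    if focal.strand == "-":
        window = window[::-1]
        truncated_upstream, truncated_downstream = right_truncated, left_truncated
    else:
        truncated_upstream, truncated_downstream = left_truncated, right_truncated

    def _label(g: GeneRecord) -> str | None:
        if labels is not None:
            return labels.get(g.gene_id)
        return g.family_id

    return Neighborhood(
        genome_id=genome.genome_id,
        focal_gene_id=focal_gene_id,
        genes=list(window),
        labels=[_label(g) for g in window],
        truncated_upstream=truncated_upstream,
        truncated_downstream=truncated_downstream,
    )


def neighborhood_frequency(neighborhoods: Iterable[Neighborhood]) -> dict[str, float]:
    """Fraction of genomes whose neighborhood contains each subfamily.

    Frequency = genomes possessing at least one member of the subfamily in
    their neighborhood, divided by the total number of genomes surveyed.
    """
    neighborhoods = list(neighborhoods)
    if not neighborhoods:
        raise ValueError("at least one neighborhood required")
    genome_ids = [nb.genome_id for nb in neighborhoods]
    if len(set(genome_ids)) != len(genome_ids):
        raise ValueError("duplicate genome ids; supply one neighborhood per genome")
    n = len(neighborhoods)
    freq: dict[str, float] = {}
    for nb in neighborhoods:
        for label in {lab for lab in nb.labels if lab is not None}:
            freq[label] = freq.get(label, 0.0) + 1.0
    return {label: count / n for label, count in freq.items()}


def classify_synteny(
    neighborhood: Neighborhood,
    island: IslandSpec | None = None,
    partner_label: str | None = None,
    peroxidase_labels: tuple[str, str] | None = None,
    max_offset: int | None = None,
) -> str:
    """Classify a focal-gene neighborhood as idr-like, aio-like, or ambiguous.

    idr-like requires the partner family AND both peroxidase families
    within the window; aio-like requires the partner and zero peroxidase
    families; anything else is ambiguous.  ``max_offset`` restricts the
    window to genes within that many positions of the focal locus (strict
    adjacency mode uses 2); the default considers the whole neighborhood.

    Labels default to the island spec's family ids; pass ``partner_label``
    and ``peroxidase_labels`` when the neighborhood is labelled with
    assigned subfamily ids instead of ground-truth family ids.
    """
    if partner_label is None or peroxidase_labels is None:
        island = island or IslandSpec()
        partner_label = partner_label or island.partner_family_id
        peroxidase_labels = peroxidase_labels or island.peroxidase_family_ids

    if max_offset is None:
        labels = set(neighborhood.labels)
    else:
        labels = {
            lab
            for off, lab in zip(neighborhood.offsets(), neighborhood.labels)
            if abs(off) <= max_offset
        }
    labels.discard(None)

    has_partner = partner_label in labels
    n_perox = sum(p in labels for p in peroxidase_labels)
    if has_partner and n_perox == 2:
        return IDR_LIKE
    if has_partner and n_perox == 0:
        return AIO_LIKE
    return AMBIGUOUS
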