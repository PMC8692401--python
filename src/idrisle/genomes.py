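"""Core containers for annotated genomes.

Coordinates are 0-based half-open internally; the GFF3 reader/writer in
:mod:`idrisle.io` converts to and from the 1-based inclusive convention at
the file boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GeneRecord:
    """A single protein-coding gene on a contig.

    ``family_id`` carries the ground-truth protein family when the genome
    was simulated, or an assigned subfamily label after clustering; it may
    be ``None`` for real annotations.
    """

    gene_id: str
    contig_id: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str  # '+' or '-'
    protein: str
    family_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid coordinates [{self.start}, {self.end}) for {self.gene_id}"
            )


@dataclass
class Genome:
    """An annotated genome: ordered, stranded genes grouped by contig."""

    genome_id: str
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene id {g.gene_id!r} in {self.genome_id}")
            seen.add(g.gene_id)

    def contigs(self) -> list[str]:
        out: list[str] = []
        for g in self.genes:
            if g.contig_id not in out:
                out.append(g.contig_id)
        return out

    def genes_on_contig(self, contig_id: str) -> list[GeneRecord]:
        """Genes on one contig sorted by genomic coordinate."""
        sel = [g for g in self.genes if g.contig_id == contig_id]
        return sorted(sel, key=lambda g: (g.start, g.end))

    def get_gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(f"gene {gene_id!r} not found in genome {self.genome_id}")

    def proteins(self) -> dict[str, str]:
        return {g.gene_id: g.protein for g in self.genes}
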