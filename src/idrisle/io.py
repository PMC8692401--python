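"""Readers and writers for the pipeline's standard formats, plus config.

FASTA goes through Biopython; GFF3 is read and written here directly (the
features are plain CDS records with ID/family attributes, and keeping one
conversion point avoids coordinate drift: files are 1-based inclusive,
everything in memory is 0-based half-open).  Tables are UTF-8 TSV with a
header row.  The pipeline configuration is a YAML file that round-trips
losslessly and rejects unknown keys.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genomes import GeneRecord, Genome
from .survey import OrfRecord
from .synthetic import ENV_VARIABLES


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file -> ordered id -> sequence map."""
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise ValueError(f"{path}: duplicate sequence id {record.id!r}")
        out[record.id] = str(record.seq)
    if not out:
        raise ValueError(f"{path}: no FASTA records")
    return out


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3


def write_genome_gff3(genome: Genome, path: str | Path) -> None:
    """Write CDS features; internal [start, end) becomes 1-based inclusive."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for gene in genome.genes:
            attrs = f"ID={gene.gene_id}"
            if gene.family_id is not None:
                attrs += f";family={gene.family_id}"
            fh.write(
                "\t".join(
                    [
                        gene.contig_id,
                        "idrisle",
                        "CDS",
                        str(gene.start + 1),
                        str(gene.end),
                        ".",
                        gene.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(
    path: str | Path,
    genome_id: str | None = None,
    proteins: dict[str, str] | None = None,
) -> Genome:
    """Parse CDS features back into a Genome.

    GFF3 coordinates are 1-based inclusive and converted to 0-based
    half-open on entry.  ``proteins`` supplies sequences by gene id (e.g.
    from the companion FASTA); absent ids get empty protein placeholders
    replaced by a single 'X' residue.
    """
    genes: list[GeneRecord] = []
    gid = genome_id or Path(path).stem
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
            contig, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype != "CDS":
                continue
            try:
                start_1b, end_1b = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: strand must be + or -, got {strand!r}")
            attr_map: dict[str, str] = {}
            for item in attrs.split(";"):
                if item and "=" in item:
                    key, value = item.split("=", 1)
                    attr_map[key] = value
            if "ID" not in attr_map:
                raise ValueError(f"{path}:{lineno}: CDS feature lacks ID attribute")
            gene_id = attr_map["ID"]
            protein = (proteins or {}).get(gene_id, "X")
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    contig_id=contig,
                    start=start_1b - 1,
                    end=end_1b,
                    strand=strand,
                    protein=protein,
                    family_id=attr_map.get("family"),
                )
            )
    return Genome(genome_id=gid, genes=genes)


# ---------------------------------------------------------------------------
# ORF catalogs


_COUNTS_COLUMNS = ["sample_id", "orf_id", "length_bp", "read_count"]


def write_counts_tsv(orfs: list[OrfRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": o.sample_id,
                "orf_id": o.orf_id,
                "length_bp": o.length_bp,
                "read_count": o.read_count,
            }
            for o in orfs
        ],
        columns=_COUNTS_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_orf_catalog(fasta_path: str | Path, counts_path: str | Path) -> list[OrfRecord]:
    """Combine a protein FASTA with a per-ORF counts TSV into OrfRecords."""
    proteins = read_fasta(fasta_path)
    table = pd.read_csv(counts_path, sep="\t")
    missing_cols = set(_COUNTS_COLUMNS) - set(table.columns)
    if missing_cols:
        raise ValueError(f"{counts_path}: missing columns {sorted(missing_cols)}")
    orfs: list[OrfRecord] = []
    for row in table.itertuples(index=False):
        if row.orf_id not in proteins:
            raise ValueError(f"{counts_path}: ORF {row.orf_id!r} absent from {fasta_path}")
        orfs.append(
            OrfRecord(
                sample_id=str(row.sample_id),
                orf_id=str(row.orf_id),
                length_bp=int(row.length_bp),
                read_count=int(row.read_count),
                protein=proteins[row.orf_id],
            )
        )
    return orfs


# ---------------------------------------------------------------------------
# Environmental metadata


def write_env_tsv(env: pd.DataFrame, path: str | Path) -> None:
    env.to_csv(path, sep="\t", index=True, index_label="sample_id", na_rep="NA")


def read_env_tsv(path: str | Path) -> pd.DataFrame:
    """Metadata TSV with the ten canonical variable names, NaN for NA."""
    table = pd.read_csv(path, sep="\t", index_col="sample_id", na_values=["NA", ""])
    for name in ENV_VARIABLES:
        if name not in table.columns:
            raise ValueError(f"{path}: missing required column {name!r}")
    return table[list(ENV_VARIABLES)]


# ---------------------------------------------------------------------------
# Pipeline configuration


@dataclass
class PipelineConfig:
    """Every stage parameter of the end-to-end pipeline, in one file."""

    seed: int = 42
    out_dir: str = "idrisle_out"
    # simulation sizes
    n_ingroup: int = 2
    n_outgroup: int = 2
    n_decoy_genomes: int = 1
    genes_per_genome: int = 60
    n_samples: int = 40
    orfs_per_sample: int = 300
    # clustering
    max_significance: float = 1e-3
    min_coverage: float = 0.5
    # neighborhoods
    window_genes: int = 10
    # profile
    pseudocount: float = 1.0
    calibration_delta: float = 1.0
    min_protein_length: int = 280
    # niche statistics
    mice_max_iter: int = 20
    mice_tol: float = 1e-6
    # energetics worked example
    delta_acetate_mm: float = 2.86
    delta_iodate_mm: float = 2.46
    delta_od600: float = 0.109
    # stage toggles
    stages: list[str] = field(
        default_factory=lambda: [
            "simulate",
            "cluster",
            "compare",
            "neighborhoods",
            "profile",
            "survey",
            "niche",
            "energetics",
        ]
    )


ALL_STAGES = (
    "simulate",
    "cluster",
    "compare",
    "neighborhoods",
    "profile",
    "survey",
    "niche",
    "energetics",
)

#: stage -> stages it needs
STAGE_DEPENDENCIES: dict[str, tuple[str, ...]] = {
    "simulate": (),
    "cluster": ("simulate",),
    "compare": ("cluster",),
    "neighborhoods": ("cluster",),
    "profile": ("neighborhoods",),
    "survey": ("profile",),
    "niche": ("survey",),
    "energetics": (),
}


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    config = PipelineConfig(**raw)
    bad = set(config.stages) - set(ALL_STAGES)
    if bad:
        raise ValueError(f"{path}: unknown stages {sorted(bad)}")
    return config


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)
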