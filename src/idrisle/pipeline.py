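"""End-to-end pipeline: simulate -> cluster -> compare -> neighborhoods ->
profile/calibrate -> survey -> niche -> energetics.

Every stage writes its artifacts (TSV/JSON, fixed numeric precision) under
the configured output directory and records inputs, parameters and seed in
a manifest.  Re-running with the same config reproduces the outputs
byte-for-byte.

The analysis stages are deliberately truth-free: the marker subfamily is
recognized as the in-group-unique subfamily with the longest proteins, the
partner and peroxidase subfamilies by their positions beside the focal
locus in the in-group neighborhoods, and the score threshold by the
peroxidase-adjacency exclusion rule — the planted truth tables are written
out for validation but never consulted by the stages themselves.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import clustering, compare, energetics, niche, survey, synteny
from . import io as iomod
from . import profile as profmod
from .io import STAGE_DEPENDENCIES, PipelineConfig
from .synthetic import (
    DecoySpec,
    IslandSpec,
    NicheModel,
    SimulationConfig,
    generate_genome_set,
    generate_metagenome,
)

logger = logging.getLogger("idrisle")

_FLOAT_FORMAT = "%.10g"


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _write_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _check_stages(stages: list[str]) -> None:
    enabled = set(stages)
    for stage in stages:
        missing = set(STAGE_DEPENDENCIES[stage]) - enabled
        if missing:
            raise StageError(stage, f"requires disabled stage(s) {sorted(missing)}")


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the configured stages in order; returns the key results.

    Raises :class:`StageError` naming the failing stage on any error.
    """
    _check_stages(config.stages)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    enabled = set(config.stages)
    results: dict[str, Any] = {}

    parameters = dataclasses.asdict(config)
    parameters.pop("out_dir")  # path is environment-specific, not a parameter
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "stages": config.stages,
        "parameters": parameters,
        "outputs": [],
    }

    def _register(name: str) -> Path:
        manifest["outputs"].append(name)
        return out_dir / name

    island = IslandSpec()

    # ----------------------------------------------------------------- simulate
    genome_set = None
    metagenome = None
    if "simulate" in enabled:
        try:
            sim = SimulationConfig(
                seed=config.seed,
                n_ingroup=config.n_ingroup,
                n_outgroup=config.n_outgroup,
                n_decoy_genomes=config.n_decoy_genomes,
                genes_per_genome=config.genes_per_genome,
                n_samples=config.n_samples,
                orfs_per_sample=config.orfs_per_sample,
            )
            genome_set = generate_genome_set(sim, island, DecoySpec())
            for genome in genome_set.genomes:
                iomod.write_fasta(genome.proteins(), _register(f"{genome.genome_id}.faa"))
                iomod.write_genome_gff3(genome, _register(f"{genome.genome_id}.gff3"))
            metagenome = generate_metagenome(sim, NicheModel())
            all_orfs = [o for s in metagenome.samples for o in s.orfs]
            iomod.write_fasta(
                {o.orf_id: o.protein for o in all_orfs}, _register("sample_orfs.faa")
            )
            iomod.write_counts_tsv(all_orfs, _register("sample_orfs.tsv"))
            iomod.write_env_tsv(metagenome.env, _register("env.tsv"))
            _write_json(
                {
                    "ingroup": genome_set.truth.ingroup_ids,
                    "outgroup": genome_set.truth.outgroup_ids,
                    "decoy": genome_set.truth.decoy_ids,
                    "island_families": list(genome_set.truth.island_families),
                    "marker_genes": genome_set.truth.marker_genes,
                    "marker_positive_samples": metagenome.truth.marker_positive,
                    "marker_orfs": metagenome.truth.marker_orfs,
                    "masked_cells": [
                        {"sample_id": s, "variable": v, "value": val}
                        for (s, v), val in sorted(metagenome.truth.masked_cells.items())
                    ],
                },
                _register("truth.json"),
            )
            logger.info(
                "simulate: %d genomes, %d samples",
                len(genome_set.genomes),
                len(metagenome.samples),
            )
        except StageError:
            raise
        except Exception as exc:
            raise StageError("simulate", str(exc)) from exc

    # ------------------------------------------------------------------ cluster
    subfamilies = None
    gene_to_genome: dict[str, str] = {}
    if "cluster" in enabled:
        try:
            assert genome_set is not None
            proteins: dict[str, str] = {}
            for genome in genome_set.genomes:
                for gene in genome.genes:
                    proteins[gene.gene_id] = gene.protein
                    gene_to_genome[gene.gene_id] = genome.genome_id
            ssn, subfamilies = clustering.cluster_proteins(
                proteins,
                max_significance=config.max_significance,
                min_coverage=config.min_coverage,
            )
            pd.DataFrame(
                [
                    {
                        "protein_id": member,
                        "subfamily_id": sf.subfamily_id,
                        "representative_flag": int(member == sf.representative_id),
                    }
                    for sf in subfamilies
                    for member in sorted(sf.member_ids)
                ]
            ).to_csv(_register("subfamilies.tsv"), sep="\t", index=False)
            pd.DataFrame(
                [
                    {
                        "protein_a": a,
                        "protein_b": b,
                        "score": data["hit"].alignment_score,
                        "identity": data["hit"].percent_identity,
                        "significance": data["hit"].significance,
                    }
                    for a, b, data in sorted(ssn.edges(data=True))
                ]
            ).to_csv(
                _register("ssn_edges.tsv"), sep="\t", index=False, float_format=_FLOAT_FORMAT
            )
            logger.info(
                "cluster: %d proteins, %d edges, %d subfamilies",
                ssn.number_of_nodes(),
                ssn.number_of_edges(),
                len(subfamilies),
            )
            results["n_subfamilies"] = len(subfamilies)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("cluster", str(exc)) from exc

    # ------------------------------------------------------------------ compare
    matrix = None
    island_subfamilies: set[str] = set()
    if "compare" in enabled:
        try:
            assert subfamilies is not None and genome_set is not None
            matrix = compare.build_matrix(subfamilies, gene_to_genome)
            matrix.astype(int).to_csv(_register("presence_absence.tsv"), sep="\t")
            island_subfamilies = compare.shared_unique(
                matrix, genome_set.truth.ingroup_ids, genome_set.truth.outgroup_ids
            )
            compare.shared_unique_report(
                matrix,
                genome_set.truth.ingroup_ids,
                genome_set.truth.outgroup_ids,
                subfamilies,
                gene_to_genome,
            ).to_csv(_register("shared_unique.tsv"), sep="\t", index=False)
            results["island_subfamilies"] = sorted(island_subfamilies)
            logger.info("compare: %d in-group-unique subfamilies", len(island_subfamilies))
        except StageError:
            raise
        except Exception as exc:
            raise StageError("compare", str(exc)) from exc

    # ------------------------------------------------------------ neighborhoods
    neighborhoods = None
    marker_subfamily = None
    partner_label: str | None = None
    peroxidase_labels: tuple[str, str] | None = None
    subfamily_of: dict[str, str] = {}
    if "neighborhoods" in enabled:
        try:
            assert subfamilies is not None and genome_set is not None
            subfamily_of = {
                member: sf.subfamily_id for sf in subfamilies for member in sf.member_ids
            }
            if not island_subfamilies:
                raise ValueError("no in-group-unique subfamilies to anchor neighborhoods")
            # marker subfamily: the in-group-unique subfamily with the longest proteins
            all_proteins = {
                g.gene_id: g.protein for genome in genome_set.genomes for g in genome.genes
            }
            mean_len = {
                sf.subfamily_id: np.mean([len(all_proteins[m]) for m in sf.member_ids])
                for sf in subfamilies
                if sf.subfamily_id in island_subfamilies
            }
            marker_subfamily = max(sorted(mean_len), key=lambda k: mean_len[k])
            focal_genes = [
                (genome, gene)
                for genome in genome_set.genomes
                for gene in genome.genes
                if subfamily_of[gene.gene_id] == marker_subfamily
            ]
            neighborhoods = [
                synteny.extract(genome, gene.gene_id, k=config.window_genes, labels=subfamily_of)
                for genome, gene in focal_genes
            ]
            # partner = subfamily immediately beside the focal locus in the
            # in-group neighborhoods; peroxidases = the remaining unique pair
            ingroup_ids = set(genome_set.truth.ingroup_ids)
            ingroup_nb = [nb for nb in neighborhoods if nb.genome_id in ingroup_ids]
            if not ingroup_nb:
                raise ValueError("no in-group neighborhood found")
            nb0 = ingroup_nb[0]
            focal_idx = nb0.focal_index
            partner_label = nb0.labels[focal_idx + 1] if focal_idx + 1 < len(nb0.labels) else None
            remaining = sorted(island_subfamilies - {marker_subfamily, partner_label})
            if partner_label is None or len(remaining) != 2:
                raise ValueError("could not resolve partner/peroxidase subfamilies")
            peroxidase_labels = (remaining[0], remaining[1])

            freq = synteny.neighborhood_frequency(neighborhoods)
            pd.DataFrame(
                sorted(freq.items()), columns=["subfamily_id", "frequency"]
            ).to_csv(_register("neighborhood_frequency.tsv"), sep="\t", index=False,
                     float_format=_FLOAT_FORMAT)
            rows = []
            for nb in neighborhoods:
                for off, gene, label in zip(nb.offsets(), nb.genes, nb.labels):
                    rows.append(
                        {
                            "genome_id": nb.genome_id,
                            "offset": off,
                            "gene_id": gene.gene_id,
                            "subfamily_id": label,
                        }
                    )
            pd.DataFrame(rows).to_csv(_register("neighborhoods.tsv"), sep="\t", index=False)
            classes = {
                nb.genome_id: synteny.classify_synteny(
                    nb, partner_label=partner_label, peroxidase_labels=peroxidase_labels
                )
                for nb in neighborhoods
            }
            _write_json(classes, _register("synteny_classes.json"))
            results["neighborhood_frequency"] = freq
            results["ingroup_neighborhood_frequency"] = synteny.neighborhood_frequency(
                ingroup_nb
            )
            results["synteny_classes"] = classes
            results["marker_subfamily"] = marker_subfamily
            logger.info("neighborhoods: %d extracted, marker=%s", len(neighborhoods), marker_subfamily)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("neighborhoods", str(exc)) from exc

    # ------------------------------------------------------------------ profile
    marker_profile = None
    calibration = None
    if "profile" in enabled:
        try:
            assert neighborhoods is not None and genome_set is not None
            ingroup_ids = set(genome_set.truth.ingroup_ids)
            member_seqs = [
                nb.genes[nb.focal_index].protein
                for nb in neighborhoods
                if nb.genome_id in ingroup_ids
            ]
            marker_profile = profmod.build_profile(member_seqs, alpha=config.pseudocount)
            genome_scores: dict[str, float] = {}
            adjacency: dict[str, bool] = {}
            for nb in neighborhoods:
                focal_protein = nb.genes[nb.focal_index].protein
                result = profmod.score_sequence(
                    marker_profile, focal_protein, min_length=config.min_protein_length
                )
                if result.filtered or result.score is None:
                    continue
                prev = genome_scores.get(nb.genome_id)
                if prev is None or result.score > prev:
                    genome_scores[nb.genome_id] = result.score
                    adjacency[nb.genome_id] = (
                        synteny.classify_synteny(
                            nb, partner_label=partner_label, peroxidase_labels=peroxidase_labels
                        )
                        == synteny.IDR_LIKE
                    )
            calibration = profmod.calibrate_threshold(
                genome_scores, adjacency, delta=config.calibration_delta
            )
            pd.DataFrame(
                [
                    {"genome_id": g, "best_score": s, "peroxidase_adjacent": int(adjacency[g])}
                    for g, s in sorted(genome_scores.items())
                ]
            ).to_csv(_register("genome_scores.tsv"), sep="\t", index=False,
                     float_format=_FLOAT_FORMAT)
            _write_json(
                {
                    "threshold": calibration.threshold,
                    "delta": calibration.delta,
                    "excluded_genomes": calibration.excluded_genomes,
                    "collateral_exclusions": calibration.collateral_exclusions,
                },
                _register("calibration.json"),
            )
            results["threshold"] = calibration.threshold
            results["genome_scores"] = genome_scores
            logger.info("profile: threshold %.1f bits", calibration.threshold)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("profile", str(exc)) from exc

    # ------------------------------------------------------------------- survey
    survey_summary = None
    hits = None
    if "survey" in enabled:
        try:
            assert marker_profile is not None and calibration is not None
            assert metagenome is not None
            hits = []
            for sample in metagenome.samples:
                hits.extend(
                    survey.search_sample(
                        marker_profile,
                        sample.orfs,
                        threshold=calibration.threshold,
                        min_length=config.min_protein_length,
                    )
                )
            sample_orfs = {s.sample_id: s.orfs for s in metagenome.samples}
            metadata = {
                s.sample_id: {"station": s.station, "depth": s.depth, "zone": s.zone}
                for s in metagenome.samples
            }
            survey_summary = survey.summarize(hits, sample_orfs, metadata)
            survey_summary.to_frame().to_csv(
                _register("survey_summary.tsv"), sep="\t", index=False,
                float_format=_FLOAT_FORMAT,
            )
            _write_json(
                {
                    "zone_fractions": survey_summary.zone_fractions,
                    "n_hits": len(hits),
                    "tpm_normalization": "whole-catalog",
                },
                _register("survey_report.json"),
            )
            results["n_survey_hits"] = len(hits)
            results["hits"] = sorted((h.sample_id, h.orf_id) for h in hits)
            results["zone_fractions"] = survey_summary.zone_fractions
            logger.info("survey: %d hits", len(hits))
        except StageError:
            raise
        except Exception as exc:
            raise StageError("survey", str(exc)) from exc

    # -------------------------------------------------------------------- niche
    if "niche" in enabled:
        try:
            assert metagenome is not None and survey_summary is not None
            imputed = niche.mice_impute(
                metagenome.env, max_iter=config.mice_max_iter, tol=config.mice_tol
            )
            pca_result = niche.pca(imputed)
            labels = niche.presence_labels(
                {s.sample_id: s.n_marker_hits for s in survey_summary.samples}
            ).reindex(imputed.index)
            binary = labels.map(lambda s: "absent" if s == "absent" else "present")
            oxygen_stats = niche.group_compare(
                imputed["Mean_Oxygen (umol/kg)"].to_numpy(), binary.to_numpy()
            )
            pca_result.scores.to_csv(_register("pca_scores.tsv"), sep="\t",
                                     float_format=_FLOAT_FORMAT)
            pca_result.loadings.to_csv(_register("pca_loadings.tsv"), sep="\t",
                                       float_format=_FLOAT_FORMAT)
            pd.DataFrame(
                {
                    "component": pca_result.scores.columns,
                    "explained_variance_ratio": pca_result.explained_variance_ratio,
                }
            ).to_csv(_register("pca_variance.tsv"), sep="\t", index=False,
                     float_format=_FLOAT_FORMAT)
            pd.DataFrame(
                [dataclasses.asdict(s) for s in oxygen_stats.values()]
            ).to_csv(_register("oxygen_group_stats.tsv"), sep="\t", index=False,
                     float_format=_FLOAT_FORMAT)
            ellipse_groups = {g for g in labels.unique() if (labels == g).sum() >= 3}
            mask = labels.isin(ellipse_groups).to_numpy()
            ellipses = niche.confidence_ellipse(
                pca_result.scores.iloc[mask.nonzero()[0], :2], labels.to_numpy()[mask]
            )
            _write_json(
                {g: dataclasses.asdict(e) for g, e in ellipses.items()},
                _register("ellipses.json"),
            )
            results["explained_variance_pc12"] = float(
                pca_result.explained_variance_ratio[:2].sum()
            )
            results["oxygen_group_stats"] = {
                g: dataclasses.asdict(s) for g, s in oxygen_stats.items()
            }
            results["pc1_loadings"] = pca_result.loadings["PC1"].to_dict()
            logger.info(
                "niche: PC1+PC2 variance %.3f", results["explained_variance_pc12"]
            )
        except StageError:
            raise
        except Exception as exc:
            raise StageError("niche", str(exc)) from exc

    # --------------------------------------------------------------- energetics
    if "energetics" in enabled:
        try:
            measurement = energetics.GrowthMeasurement(
                delta_acetate_mm=config.delta_acetate_mm,
                delta_iodate_mm=config.delta_iodate_mm,
                delta_od600=config.delta_od600,
            )
            stoich = energetics.assimilation_correction(measurement)
            balance = energetics.electron_balance()
            ledger = energetics.disproportionation_ledger(3.0)
            report = {
                "observed_ratio": stoich.observed_ratio,
                "assimilated_acetate_mm": stoich.assimilated_acetate_mm,
                "assimilated_carbon_fraction": stoich.assimilated_carbon_fraction,
                "respired_acetate_mm": stoich.respired_acetate_mm,
                "theoretical_ratio": stoich.theoretical_ratio,
                "percent_of_theoretical": stoich.percent_of_theoretical,
                "electron_balance": {
                    "donor_electrons": balance.donor_electrons,
                    "acceptor_electrons": balance.acceptor_electrons,
                    "balanced": balance.balanced,
                },
                "gibbs_per_electron_kj": energetics.gibbs_per_electron(
                    energetics.IODATE_IODIDE, energetics.ACETATE_CO2
                ),
                "ledger": {
                    "initial_iodate": ledger.initial_iodate,
                    "enzymatic_turnovers": ledger.enzymatic_turnovers,
                    "net_iodide": ledger.net_iodide,
                    "electrons_transferred": ledger.electrons_transferred,
                    "cycles_to_converge": ledger.cycles_to_converge,
                },
            }
            _write_json(report, _register("energetics.json"))
            results["energetics"] = report
            logger.info(
                "energetics: %.0f%% of theoretical demand", stoich.percent_of_theoretical
            )
        except StageError:
            raise
        except Exception as exc:
            raise StageError("energetics", str(exc)) from exc

    _write_json(manifest, out_dir / "manifest.json")
    return results
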