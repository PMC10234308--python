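"""End-to-end orchestration: files -> features -> labels -> ensemble ->
interpretation.

This module wires the per-module operations together for a cohort laid
out as genome FASTA + GTF + branchpoint TSV + TPM tables + metadata TSV
(the layout `synthetic_data.generate_cohort` emits and the CLI consumes).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from . import (
    expression_labels,
    feature_assembly,
    genome_io,
    interpretation,
    motif_scoring,
    predictor,
    structure_features,
)
from .feature_assembly import FeatureTable
from .synthetic_data import CohortPaths

logger = logging.getLogger(__name__)


@dataclass
class CohortFeatures:
    table: FeatureTable
    records: list[genome_io.SnoRecord]
    box_scores: dict[str, motif_scoring.BoxScore]
    raw: pd.DataFrame


def compute_feature_table(
    genome_fa: str | Path,
    gtf: str | Path,
    metadata_tsv: str | Path,
    sno_tpm_tsv: str | Path,
    host_tpm_tsv: str | Path,
    design_tsv: str | Path,
    branchpoints_tsv: str | Path | None = None,
    engine: str = "vienna",
    impute: str = "zero",
    tpm_threshold: float = expression_labels.DEFAULT_THRESHOLD,
) -> CohortFeatures:
    """Compute, label, and encode the full feature matrix for a cohort."""
    annotation = genome_io.read_annotation(gtf)
    fasta = Fasta(str(genome_fa))
    metadata = pd.read_csv(metadata_tsv, sep="\t", index_col=0)
    records = genome_io.read_snorna_records(
        annotation, fasta, metadata["sno_type"].to_dict()
    )
    fold_engine = structure_features.get_engine(engine)
    host_genes = {}
    for gene in annotation.genes.values():
        if gene.biotype != "snoRNA":
            host_genes.setdefault((gene.interval.chrom, gene.interval.strand), []).append(gene)

    branchpoints = (
        genome_io.read_branchpoints(branchpoints_tsv)
        if branchpoints_tsv is not None
        else None
    )

    assignments: dict[str, genome_io.HostAssignment] = {}
    contexts: dict[str, genome_io.IntronContext | None] = {}
    box_scores: dict[str, motif_scoring.BoxScore] = {}
    structure_rows = []
    for rec in records:
        fold = structure_features.fold_global(rec.sequence, fold_engine)
        box_scores[rec.id] = motif_scoring.box_score(
            rec.sequence, rec.sno_type, fold.structure
        )
        up, down = genome_io.extract_flanks(rec, fasta)
        s5, s3 = structure_features.build_stem_strands(rec.sequence, rec.sno_type, up, down)
        duplex = structure_features.cofold_stem(s5, s3, fold_engine)
        structure_rows.append(
            {
                "sno_id": rec.id,
                "sno_stability": fold.mfe,
                "terminal_stem_stability": duplex.mfe,
                "terminal_stem_length_score": structure_features.stem_length_score(duplex),
            }
        )

        key = (rec.interval.chrom, rec.interval.strand)
        assignment = genome_io.assign_host(rec, host_genes.get(key, []))
        assignments[rec.id] = assignment
        ctx = None
        if not assignment.is_intergenic:
            ctx = genome_io.derive_intron_context(
                rec, annotation.transcripts_of(assignment.host_id)
            )
            if ctx is not None and branchpoints is not None:
                iv = ctx.intron_interval
                in_intron = branchpoints[
                    (branchpoints["chrom"] == iv.chrom)
                    & (branchpoints["pos"] >= iv.start)
                    & (branchpoints["pos"] < iv.end)
                ]
                ctx.dist_branchpoint = genome_io.distance_to_branchpoint(rec, in_intron)
        contexts[rec.id] = ctx
    structure = pd.DataFrame(structure_rows).set_index("sno_id")

    sno_means = expression_labels.average_by_tissue(
        expression_labels.read_tpm_table(sno_tpm_tsv),
        expression_labels.read_design(design_tsv),
    )
    sno_labels = expression_labels.label_expression(sno_means, tpm_threshold)
    host_means = expression_labels.average_by_tissue(
        expression_labels.read_tpm_table(host_tpm_tsv),
        expression_labels.read_design(design_tsv),
    )
    host_labels = expression_labels.label_expression(host_means, tpm_threshold)
    host_status = expression_labels.host_expression_status(host_labels, assignments)

    categorical = pd.DataFrame(
        {
            "target": metadata["target"],
            "host_biotype": pd.Series(
                {i: a.host_biotype for i, a in assignments.items()}
            ),
            "host_function": metadata["host_function"],
            "nmd_susceptibility": metadata["nmd_susceptibility"],
            "dual_initiation_promoter": metadata["dual_initiation_promoter"],
        }
    )
    raw = feature_assembly.assemble_features(
        records,
        box_scores,
        structure,
        contexts,
        host_status.to_dict(),
        sno_labels["status"].to_dict(),
        categorical,
        impute=impute,
    )
    table = feature_assembly.one_hot_encode(raw)
    return CohortFeatures(table, records, box_scores, raw)


def compute_feature_table_for_cohort(
    paths: CohortPaths, engine: str = "vienna", **kwargs
) -> CohortFeatures:
    return compute_feature_table(
        paths.genome,
        paths.gtf,
        paths.metadata,
        paths.sno_tpm,
        paths.host_tpm,
        paths.design,
        branchpoints_tsv=paths.branchpoints,
        engine=engine,
        **kwargs,
    )


@dataclass
class AnalysisResult:
    features: CohortFeatures
    protocol: predictor.ProtocolResult
    metrics: dict
    rank_table: pd.DataFrame
    aggregate_ranks: pd.DataFrame


def interpret_protocol(
    features: CohortFeatures,
    protocol: predictor.ProtocolResult,
    seed: int = 0,
    families: Sequence[str] | None = None,
    max_rows: int = 100,
    max_background: int = 100,
    n_samples: int = 16,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attribute every (family, iteration) model on its own test rows and
    aggregate mean-|contribution| ranks across models and iterations.

    Rows and background are capped (seeded subsample) to keep the
    sampling approximation tractable at cohort scale.
    """
    families = tuple(families or protocol.ensemble_families)
    X_all = features.table.X[
        list(protocol.scalers[0].mean.index)
    ]
    rng = np.random.default_rng(seed)
    matrices: dict[tuple[str, int], interpretation.AttributionMatrix] = {}
    for k, split in enumerate(protocol.plan.iterations):
        stats = protocol.scalers[k]
        X_train = feature_assembly.apply_scaler(stats, X_all.loc[list(split.training)])
        X_test = feature_assembly.apply_scaler(stats, X_all.loc[list(split.test)])
        if len(X_train) > max_background:
            bg_idx = rng.choice(len(X_train), size=max_background, replace=False)
            background = X_train.iloc[np.sort(bg_idx)]
        else:
            background = X_train
        rows = X_test
        if len(rows) > max_rows:
            row_idx = rng.choice(len(rows), size=max_rows, replace=False)
            rows = rows.iloc[np.sort(row_idx)]
        for family in families:
            model = protocol.models[(family, k)]
            matrices[(family, k)] = interpretation.attribute(
                model,
                rows,
                background,
                seed=(seed + 104729 * (k + 1)) % (2**31 - 1),
                n_samples=n_samples,
                exact_max_features=0 if len(X_all.columns) > 8 else 8,
            )
    rank_table = interpretation.rank_features(matrices)
    return rank_table, interpretation.aggregate_ranks(rank_table)


def run_end_to_end(
    cohort_dir: str | Path,
    seed: int = 0,
    n_iter: int = 10,
    families: Sequence[str] = predictor.ENSEMBLE_FAMILIES,
    engine: str = "vienna",
    outdir: str | Path | None = None,
) -> AnalysisResult:
    """Features -> labels -> ensemble protocol -> metrics -> ranks for one
    cohort directory; optionally writes plot-ready TSV/JSON artifacts."""
    paths = CohortPaths.in_dir(cohort_dir)
    features = compute_feature_table_for_cohort(paths, engine=engine)
    protocol = predictor.run_protocol(
        features.table, seed=seed, n_iter=n_iter, families=families,
        ensemble_families=families if len(families) == 3 else predictor.ENSEMBLE_FAMILIES,
    )
    metrics = predictor.confusion_and_metrics(protocol.predictions)
    rank_table, agg = interpret_protocol(features, protocol, seed=seed)
    result = AnalysisResult(features, protocol, metrics, rank_table, agg)
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def write_outputs(result: AnalysisResult, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "predictions": outdir / "predictions.tsv",
        "metrics": outdir / "metrics.json",
        "ranks": outdir / "feature_ranks.tsv",
        "aggregate_ranks": outdir / "aggregate_ranks.tsv",
    }
    result.protocol.predictions.to_csv(paths["predictions"], sep="\t", float_format="%.6g")
    serializable = {
        k: v for k, v in result.metrics.items() if not isinstance(v, pd.DataFrame)
    }
    with open(paths["metrics"], "w") as fh:
        json.dump(serializable, fh, indent=1, sort_keys=True)
        fh.write("\n")
    result.rank_table.to_csv(paths["ranks"], sep="\t", index=False, float_format="%.6g")
    result.aggregate_ranks.to_csv(paths["aggregate_ranks"], sep="\t", float_format="%.6g")
    return paths
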