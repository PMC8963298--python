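"""End-to-end orchestration of the QC workflow.

Actions, in order: optional median batch normalization; summary
statistics on the (normalized) raw data including feature reduction and
PCA; the ordered exclusion pipeline; summary statistics on the filtered
data; batch-effect and power analyses; export of all tables, the HTML
report and the per-feature plot document.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .batcheffects import batch_effect_table
from .config import PipelineConfig
from .datatypes import AbundanceMatrix, ExclusionLog, FeatureAnnotation, SampleMetadata
from .decompose import (
    PcaResult,
    acceleration_factor_n,
    cluster_features,
    eligible_features,
    handle_outlier_values,
    impute_standardize,
    parallel_analysis_n,
    pc_outliers,
    run_pca,
)
from .filters import apply_filter_pipeline
from .io import write_tables
from .normalize import median_batch_normalize
from .power import power_grid_for_missingness
from .report import render_feature_document, render_report
from .summaries import (
    exclusion_feature_set,
    feature_summary_table,
    outlier_flags,
    sample_summary_table,
)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    raw_matrix: AbundanceMatrix
    filtered_matrix: AbundanceMatrix
    raw_sample_summary: pd.DataFrame
    raw_feature_summary: pd.DataFrame
    filtered_sample_summary: pd.DataFrame
    filtered_feature_summary: pd.DataFrame
    exclusion_log: ExclusionLog
    clustering: object
    pca: PcaResult | None
    batch_table: pd.DataFrame | None
    batch_notes: list[str]
    power_curves: list
    output_paths: dict


def _summaries(matrix, annotation, config):
    """Sample/feature summaries plus reduction + PCA for one dataset state."""
    clustering = None
    pca = None
    try:
        working = matrix
        if config.pca_outlier_mode != "leave":
            flags, _, _ = outlier_flags(matrix, config.outlier_iqr_multiplier)
            working = handle_outlier_values(matrix, flags, config.pca_outlier_mode)
        elig = eligible_features(working, annotation, config)
        clustering = cluster_features(working, elig, config.tree_cut_height)
        z = impute_standardize(working, clustering.representatives)
        pca = run_pca(z)
        pca.n_accel = acceleration_factor_n(pca.eigenvalues, config.pc_min_components)
        pca.n_parallel = parallel_analysis_n(
            pca.eigenvalues, z.shape[0], z.shape[1], seed=config.rng_seed
        )
        pca.outlier_sample_ids = pc_outliers(
            pca.scores, pca.n_accel, config.pc_sd_threshold
        )
    except ValueError as exc:
        warnings.warn(f"reduction/PCA skipped: {exc}")
    reps = clustering.representatives if clustering is not None else ()
    scores = pca.scores if pca is not None else None
    sample_summary = sample_summary_table(
        matrix,
        annotation,
        exclude_derived=config.exclude_derived,
        outlier_iqr_multiplier=config.outlier_iqr_multiplier,
        pc_scores=scores,
    )
    feature_summary = feature_summary_table(
        matrix,
        outlier_iqr_multiplier=config.outlier_iqr_multiplier,
        representative_ids=reps,
        seed=config.rng_seed,
    )
    return sample_summary, feature_summary, clustering, pca


def run_pipeline(
    matrix: AbundanceMatrix,
    annotation: FeatureAnnotation | None,
    meta: SampleMetadata | None,
    config: PipelineConfig,
    outdir,
    project: str = "metaboqc run",
    platform: str = "unspecified",
    write_report: bool = True,
    feature_document: bool = True,
) -> PipelineResult:
    """Run the full QC workflow and write all artifacts into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation = (
        annotation.aligned(matrix.feature_ids)
        if annotation is not None
        else FeatureAnnotation.empty(matrix.feature_ids)
    )

    if config.batch_normalization_column:
        if meta is None:
            raise ValueError("batch normalization requested but no sample metadata given")
        matrix = median_batch_normalize(matrix, meta, config.batch_normalization_column)

    raw_ss, raw_fs, _, _ = _summaries(matrix, annotation, config)
    filtered, log = apply_filter_pipeline(matrix, annotation, meta, config)
    filt_ann = annotation.aligned(filtered.feature_ids)
    filt_ss, filt_fs, clustering, pca = _summaries(filtered, filt_ann, config)

    batch_table, batch_notes = None, []
    meta_df = None
    if meta is not None:
        meta_df = meta.aligned(matrix.sample_ids)
        batch_table, batch_notes = batch_effect_table(raw_ss, meta_df)

    power_curves = power_grid_for_missingness(
        filtered.n_samples, filt_fs["missingness"]
    )

    paths = write_tables(
        outdir,
        raw_matrix=matrix,
        filtered_matrix=filtered,
        raw_sample_summary=raw_ss,
        raw_feature_summary=raw_fs,
        filtered_sample_summary=filt_ss,
        filtered_feature_summary=filt_fs,
        exclusion_log=log,
    )
    if write_report:
        paths["report"] = render_report(
            outdir / "qc_report.html",
            config=config,
            raw_matrix=matrix,
            raw_sample_summary=raw_ss,
            raw_feature_summary=raw_fs,
            filtered_sample_summary=filt_ss,
            filtered_feature_summary=filt_fs,
            clustering=clustering,
            pca=pca,
            exclusion_log=log,
            batch_table=batch_table,
            batch_notes=batch_notes,
            sample_metadata=meta_df,
            power_curves=power_curves,
            project=project,
            platform=platform,
        )
    if feature_document:
        flags, _, _ = outlier_flags(filtered, config.outlier_iqr_multiplier)
        paths["feature_document"] = render_feature_document(
            filtered, filt_fs, flags, outdir / "feature_plots.pdf"
        )

    return PipelineResult(
        raw_matrix=matrix,
        filtered_matrix=filtered,
        raw_sample_summary=raw_ss,
        raw_feature_summary=raw_fs,
        filtered_sample_summary=filt_ss,
        filtered_feature_summary=filt_fs,
        exclusion_log=log,
        clustering=clustering,
        pca=pca,
        batch_table=batch_table,
        batch_notes=batch_notes,
        power_curves=power_curves,
        output_paths=paths,
    )
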