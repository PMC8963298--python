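"""The ordered sample/feature exclusion pipeline.

Steps, in order:

1. samples with extreme missingness (>= 80%);
2. features with extreme missingness (>= 80%), xenobiotics exempt;
3. samples above the user missingness threshold (recomputed);
4. features above the user missingness threshold, xenobiotics exempt;
5. samples whose TSA over complete features is more than the threshold
   number of SDs from the mean;
6. samples beyond the PC threshold on the top components of a PCA of
   the surviving representative features (component count from the
   acceleration factor, minimum 2).

Missingness exclusions use ``>= threshold``; TSA/PC exclusions use
strictly ``> threshold`` SDs. User missingness thresholds of 0 disable
steps 3-4 (a documented no-exclusion setting). The filtered matrix
keeps the original value scale: the imputation/winsorization used for
PCA is never persisted.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .datatypes import AbundanceMatrix, ExclusionLog, FeatureAnnotation, SampleMetadata
from .decompose import (
    acceleration_factor_n,
    cluster_features,
    eligible_features,
    handle_outlier_values,
    impute_standardize,
    pc_outliers,
    run_pca,
)
from .summaries import (
    exclusion_feature_set,
    feature_missingness,
    outlier_flags,
    sample_missingness,
    total_sum_abundance,
)

__all__ = ["apply_filter_pipeline"]


def _check_nonempty(df: pd.DataFrame, step: str) -> None:
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"matrix is empty after step {step!r}")


def apply_filter_pipeline(
    matrix: AbundanceMatrix,
    annotation: FeatureAnnotation,
    meta: SampleMetadata | None,
    config: PipelineConfig,
) -> tuple[AbundanceMatrix, ExclusionLog]:
    """Run the six-step exclusion pipeline; returns the filtered matrix
    and the ordered exclusion log.

    If batch normalization is configured it must already have been
    applied to ``matrix``.
    """
    df = matrix.data.copy()
    ann = annotation.aligned(matrix.feature_ids)
    log = ExclusionLog()

    def current_excl() -> set[str]:
        return exclusion_feature_set(ann, config.exclude_derived) & set(df.columns)

    def exempt_features() -> set[str]:
        # xenobiotics always survive missingness filters; derived measures
        # pass through untouched when they are excluded from computations
        ex = set(ann.xenobiotic_ids())
        if config.exclude_derived:
            ex |= set(ann.derived_ids())
        return ex & set(df.columns)

    def drop_samples(name: str, threshold: str, ids: list[str]) -> None:
        nonlocal df
        n_before = df.shape[0]
        df = df.drop(index=ids)
        log.add(
            name=name,
            entity="sample",
            threshold=threshold,
            removed_ids=ids,
            n_before=n_before,
            n_after=df.shape[0],
        )
        _check_nonempty(df, name)

    def drop_features(name: str, threshold: str, ids: list[str]) -> None:
        nonlocal df
        n_before = df.shape[1]
        df = df.drop(columns=ids)
        log.add(
            name=name,
            entity="feature",
            threshold=threshold,
            removed_ids=ids,
            n_before=n_before,
            n_after=df.shape[1],
        )
        _check_nonempty(df, name)

    def sample_miss() -> pd.Series:
        am = AbundanceMatrix(df)
        excl = current_excl()
        if len(excl) >= df.shape[1]:
            return sample_missingness(am)
        return sample_missingness(am, excl)

    ext = config.extreme_missingness

    # 1. extreme sample missingness
    sm = sample_miss()
    drop_samples(
        "extreme_sample_missingness", f">={ext:.0%}", list(sm.index[sm >= ext])
    )

    # 2. extreme feature missingness (xenobiotics exempt)
    fm = feature_missingness(AbundanceMatrix(df))
    exempt = exempt_features()
    ids = [f for f in df.columns if fm[f] >= ext and f not in exempt]
    drop_features("extreme_feature_missingness", f">={ext:.0%}", ids)

    # 3. user sample missingness
    thr = config.sample_missingness_max
    if thr == 0:
        drop_samples("sample_missingness", "disabled", [])
    else:
        sm = sample_miss()
        drop_samples(
            "sample_missingness", f">={thr:.0%}", list(sm.index[sm >= thr])
        )

    # 4. user feature missingness (xenobiotics exempt)
    thr = config.feature_missingness_max
    if thr == 0:
        drop_features("feature_missingness", "disabled", [])
    else:
        fm = feature_missingness(AbundanceMatrix(df))
        exempt = exempt_features()
        ids = [f for f in df.columns if fm[f] >= thr and f not in exempt]
        drop_features("feature_missingness", f">={thr:.0%}", ids)

    # 5. TSA over complete features
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tsa = total_sum_abundance(
            AbundanceMatrix(df), complete_only=True, excluded_features=current_excl()
        )
    thr = config.tsa_sd_threshold
    if tsa.notna().any():
        mean, sd = tsa.mean(), tsa.std(ddof=1)
        ids = [] if not sd > 0 else list(tsa.index[(tsa - mean).abs() > thr * sd])
    else:
        warnings.warn("no complete features; TSA exclusion step removed nothing")
        ids = []
    drop_samples("sample_tsa", f">{thr:g}SD", ids)

    # 6. PC outliers on the surviving representative features
    thr = config.pc_sd_threshold
    ids = []
    try:
        am = AbundanceMatrix(df)
        working = am
        if config.pca_outlier_mode != "leave":
            flags, _, _ = outlier_flags(am, config.outlier_iqr_multiplier)
            working = handle_outlier_values(am, flags, config.pca_outlier_mode)
        elig = eligible_features(working, ann, config)
        clust = cluster_features(working, elig, config.tree_cut_height)
        z = impute_standardize(working, clust.representatives)
        pca = run_pca(z)
        n = acceleration_factor_n(pca.eigenvalues, config.pc_min_components)
        ids = pc_outliers(pca.scores, n, thr)
    except ValueError as exc:
        warnings.warn(f"PC outlier step skipped: {exc}")
    drop_samples("sample_pca_outliers", f">{thr:g}SD", ids)

    return AbundanceMatrix(df), log
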