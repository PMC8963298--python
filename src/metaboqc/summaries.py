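"""Per-sample and per-feature quality statistics.

Sample metrics: missingness (with and without the configured exclusion
class), total sum abundance (TSA, a.k.a. total peak area) over all and
over complete features, and a count of extreme-value occurrences.
Feature metrics: missingness, n, mean, SD, skew, CV, Shapiro-Wilk W on
raw and log10 scales, and an outlier count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AbundanceMatrix, FeatureAnnotation

__all__ = [
    "sample_missingness",
    "feature_missingness",
    "total_sum_abundance",
    "outlier_flags",
    "feature_descriptives",
    "normality_w",
    "ShapiroResult",
    "sample_summary_table",
    "feature_summary_table",
    "exclusion_feature_set",
]

SHAPIRO_MAX_N = 5000


def exclusion_feature_set(annotation: FeatureAnnotation, exclude_derived: bool) -> set[str]:
    """Features excluded from sample-level metrics: xenobiotics always,
    derived measures when configured."""
    ids = set(annotation.xenobiotic_ids())
    if exclude_derived:
        ids |= set(annotation.derived_ids())
    return ids


def sample_missingness(matrix: AbundanceMatrix, excluded_features=()) -> pd.Series:
    """Fraction of missing entries per sample over non-excluded features."""
    excluded = set(excluded_features)
    unknown = excluded.difference(matrix.feature_ids)
    if unknown:
        raise ValueError(f"excluded features not in matrix: {sorted(unknown)[:5]}")
    keep = [f for f in matrix.feature_ids if f not in excluded]
    if not keep:
        raise ValueError("all features excluded from sample missingness")
    sub = matrix.data[keep]
    return sub.isna().sum(axis=1) / len(keep)


def feature_missingness(matrix: AbundanceMatrix) -> pd.Series:
    """Fraction of missing entries per feature."""
    if matrix.n_samples < 1:
        raise ValueError("matrix has no samples")
    return matrix.data.isna().sum(axis=0) / matrix.n_samples


def _zscore(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.Index]:
    """Column z-scores over non-missing entries (ddof=1); returns the
    standardized frame and the columns dropped for zero/undefined variance."""
    mean = df.mean(axis=0)
    sd = df.std(axis=0, ddof=1)
    degenerate = df.columns[(sd == 0) | sd.isna()]
    keep = df.columns.difference(degenerate, sort=False)
    z = (df[keep] - mean[keep]) / sd[keep]
    return z, degenerate


def total_sum_abundance(
    matrix: AbundanceMatrix,
    complete_only: bool = False,
    excluded_features=(),
) -> pd.Series:
    """Total sum abundance per sample.

    Retained features are z-transformed over their non-missing entries,
    every standardized entry is shifted up by the absolute value of the
    global minimum of the standardized matrix, and the shifted values
    are summed per sample (missing entries contribute nothing). With
    ``complete_only`` the sum runs over features with no missing data.
    """
    if matrix.n_samples < 2:
        raise ValueError("TSA requires at least 2 samples")
    excluded = set(excluded_features)
    keep = [f for f in matrix.feature_ids if f not in excluded]
    sub = matrix.data[keep]
    if complete_only:
        complete = sub.columns[sub.notna().all(axis=0)]
        if len(complete) == 0:
            warnings.warn("no complete features; TSA(complete) is missing")
            return pd.Series(np.nan, index=matrix.data.index)
        sub = sub[complete]
    z, degenerate = _zscore(sub)
    if len(degenerate):
        warnings.warn(
            f"{len(degenerate)} zero-variance feature(s) excluded from TSA"
        )
    if z.shape[1] == 0:
        warnings.warn("no variable features; TSA is missing")
        return pd.Series(np.nan, index=matrix.data.index)
    m = np.nanmin(z.to_numpy())
    shifted = z + abs(m)
    return shifted.sum(axis=1, skipna=True)


def outlier_flags(matrix: AbundanceMatrix, k: float = 5.0):
    """Flag cells more than ``k`` IQR-units from their feature median.

    Median and IQR are taken over each feature's non-missing entries
    with linear-interpolation quantiles. Missing cells are never
    flagged. When a feature's IQR is 0, any value off the median is
    flagged (an all-equal feature therefore produces no flags).

    Returns ``(flags, per_sample_counts, per_feature_counts)``.
    """
    if not k > 0:
        raise ValueError("k must be > 0")
    df = matrix.data
    med = df.median(axis=0)
    q1 = df.quantile(0.25, axis=0, interpolation="linear")
    q3 = df.quantile(0.75, axis=0, interpolation="linear")
    iqr = q3 - q1
    flags = (df.sub(med, axis=1).abs() > k * iqr).fillna(False) & df.notna()
    return flags, flags.sum(axis=1), flags.sum(axis=0)


def feature_descriptives(matrix: AbundanceMatrix) -> pd.DataFrame:
    """n, mean, SD (n-1), adjusted Fisher-Pearson skew, and CV per feature."""
    df = matrix.data
    n = df.notna().sum(axis=0)
    mean = df.mean(axis=0)
    sd = df.std(axis=0, ddof=1)
    sd[n < 2] = np.nan
    cv = sd / mean.where(mean != 0)
    skew = pd.Series(np.nan, index=df.columns)
    for col in df.columns:
        vals = df[col].dropna().to_numpy()
        if vals.size >= 3 and np.ptp(vals) > 0:
            skew[col] = stats.skew(vals, bias=False)
    return pd.DataFrame({"n": n, "mean": mean, "sd": sd, "skew": skew, "cv": cv})


@dataclass
class ShapiroResult:
    w_raw: float
    w_log10: float
    reason_raw: str | None = None
    reason_log10: str | None = None


def _shapiro(vals: np.ndarray, rng: np.random.Generator) -> tuple[float, str | None]:
    vals = vals[~np.isnan(vals)]
    if vals.size < 4:
        return np.nan, "insufficient n"
    if np.ptp(vals) == 0:
        return np.nan, "zero variance"
    if vals.size > SHAPIRO_MAX_N:
        vals = rng.choice(vals, size=SHAPIRO_MAX_N, replace=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        w = stats.shapiro(vals).statistic
    return float(w), None


def normality_w(values, seed: int = 0) -> ShapiroResult:
    """Shapiro-Wilk W on the raw and log10 scales.

    Entries <= 0 are treated as missing for the log10 variant. Vectors
    longer than 5000 are evaluated on a seeded random subsample.
    """
    vals = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    w_raw, reason_raw = _shapiro(vals, rng)
    pos = vals[np.isfinite(vals) & (vals > 0)]
    w_log, reason_log = _shapiro(np.log10(pos), np.random.default_rng(seed))
    return ShapiroResult(w_raw, w_log, reason_raw, reason_log)


def sample_summary_table(
    matrix: AbundanceMatrix,
    annotation: FeatureAnnotation,
    exclude_derived: bool = False,
    outlier_iqr_multiplier: float = 5.0,
    pc_scores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the per-sample summary table.

    ``pc_scores`` (top principal components from the reduction/PCA
    stage) are merged in when available; absent components are NA.
    """
    excl = exclusion_feature_set(annotation, exclude_derived)
    excl &= set(matrix.feature_ids)
    _, sample_counts, _ = outlier_flags(matrix, outlier_iqr_multiplier)
    out = pd.DataFrame(index=matrix.data.index)
    out.index.name = "sample_id"
    out["missingness_all"] = sample_missingness(matrix)
    out["missingness_excl"] = (
        sample_missingness(matrix, excl) if len(excl) < matrix.n_features else np.nan
    )
    out["tsa_all"] = total_sum_abundance(matrix, complete_only=False, excluded_features=excl)
    out["tsa_complete"] = total_sum_abundance(matrix, complete_only=True, excluded_features=excl)
    out["outlier_count"] = sample_counts
    for i in range(10):
        name = f"PC{i + 1}"
        if pc_scores is not None and name in pc_scores.columns:
            out[name] = pc_scores[name].reindex(out.index)
        else:
            out[name] = np.nan
    return out


def feature_summary_table(
    matrix: AbundanceMatrix,
    outlier_iqr_multiplier: float = 5.0,
    representative_ids=(),
    seed: int = 0,
) -> pd.DataFrame:
    """Assemble the per-feature summary table.

    ``representative_ids`` (one per correlation cluster) are marked in
    the ``independent_features_binary`` column.
    """
    desc = feature_descriptives(matrix)
    _, _, feature_counts = outlier_flags(matrix, outlier_iqr_multiplier)
    out = pd.DataFrame(index=matrix.data.columns)
    out.index.name = "feature_id"
    out["missingness"] = feature_missingness(matrix)
    for col in ("n", "mean", "sd", "skew", "cv"):
        out[col] = desc[col]
    w_raw, w_log = [], []
    for col in matrix.data.columns:
        res = normality_w(matrix.data[col].to_numpy(), seed=seed)
        w_raw.append(res.w_raw)
        w_log.append(res.w_log10)
    out["w_raw"] = w_raw
    out["w_log10"] = w_log
    out["outlier_count"] = feature_counts
    reps = set(representative_ids)
    out["independent_features_binary"] = [
        1 if f in reps else 0 for f in matrix.data.columns
    ]
    return out
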