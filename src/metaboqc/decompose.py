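"""Feature reduction and sample PCA.

Representative features are chosen by complete-linkage hierarchical
clustering on a 1 - |Spearman rho| distance matrix; the least-missing
member of each cluster represents it ("effective number of features").
PCA runs on the median-imputed, standardized representative set, the
number of informative components is estimated by the scree acceleration
factor and by parallel analysis, and samples far from the mean on the
retained components are flagged as outliers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .config import PipelineConfig
from .datatypes import AbundanceMatrix, FeatureAnnotation
from .summaries import feature_missingness

__all__ = [
    "FeatureClustering",
    "PcaResult",
    "eligible_features",
    "cluster_features",
    "impute_standardize",
    "run_pca",
    "acceleration_factor_n",
    "parallel_analysis_n",
    "pc_outliers",
    "handle_outlier_values",
]

ELIGIBLE_MISSINGNESS_MAX = 0.2  # fixed inclusion rule for the reduction/PCA stage
MIN_SHARED_OBS = 3


@dataclass
class FeatureClustering:
    feature_ids: list[str]
    distance: pd.DataFrame  # 1 - |Spearman rho|, symmetric, zero diagonal
    labels: pd.Series  # cluster id per feature (1..k)
    k: int
    representatives: list[str]
    linkage_matrix: np.ndarray = field(repr=False, default=None)


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x PC1..PCm
    eigenvalues: np.ndarray  # variance of each component (n-1 denominator)
    variance_explained: np.ndarray  # fractions, non-increasing
    loadings: pd.DataFrame = field(repr=False, default=None)
    n_accel: int | None = None
    n_parallel: int | None = None
    outlier_sample_ids: list[str] = field(default_factory=list)


def eligible_features(
    matrix: AbundanceMatrix,
    annotation: FeatureAnnotation,
    config: PipelineConfig,
) -> list[str]:
    """Features admitted to the reduction/PCA stage.

    Excludes xenobiotics always, derived measures when configured,
    zero-variance features and features with more than 20% missingness.
    """
    ann = annotation.aligned(matrix.feature_ids)
    drop = set(ann.xenobiotic_ids())
    if config.exclude_derived:
        drop |= set(ann.derived_ids())
    miss = feature_missingness(matrix)
    sd = matrix.data.std(axis=0, ddof=1)
    keep = [
        f
        for f in matrix.feature_ids
        if f not in drop
        and miss[f] <= ELIGIBLE_MISSINGNESS_MAX
        and np.isfinite(sd[f])
        and sd[f] > 0
    ]
    if len(keep) < 2:
        raise ValueError(f"only {len(keep)} eligible feature(s); need at least 2")
    return keep


def cluster_features(
    matrix: AbundanceMatrix, ids, cut_height: float = 0.5
) -> FeatureClustering:
    """Complete-linkage clustering on 1 - |Spearman rho| distances.

    Spearman correlations use pairwise-complete observations; pairs with
    fewer than 3 shared observations get distance 1 with a warning.
    Clusters are the subtrees whose merge heights are all <= ``cut_height``;
    each cluster's least-missing feature is its representative (ties
    broken by input column order).
    """
    ids = list(ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 features to cluster")
    sub = matrix.data[ids]
    rho = sub.corr(method="spearman", min_periods=MIN_SHARED_OBS)
    dist = 1.0 - rho.abs()
    if dist.isna().to_numpy().any():
        n_bad = int(dist.isna().to_numpy().sum() - np.isnan(np.diag(dist)).sum()) // 2
        warnings.warn(
            f"{n_bad} feature pair(s) share < {MIN_SHARED_OBS} observations; "
            "distance set to 1"
        )
        dist = dist.fillna(1.0)
    arr = np.clip(dist.to_numpy(), 0.0, 1.0)
    np.fill_diagonal(arr, 0.0)
    arr = (arr + arr.T) / 2.0
    Z = linkage(squareform(arr, checks=False), method="complete")
    labels = pd.Series(
        fcluster(Z, t=cut_height, criterion="distance"), index=ids, name="cluster"
    )
    miss = feature_missingness(matrix)[ids]
    reps: list[str] = []
    for cl in sorted(labels.unique()):
        members = [f for f in ids if labels[f] == cl]  # input column order
        reps.append(min(members, key=lambda f: (miss[f], members.index(f))))
    return FeatureClustering(
        feature_ids=ids,
        distance=pd.DataFrame(arr, index=ids, columns=ids),
        labels=labels,
        k=int(labels.nunique()),
        representatives=reps,
        linkage_matrix=Z,
    )


def impute_standardize(matrix: AbundanceMatrix, ids) -> pd.DataFrame:
    """Median-impute missing entries, then z-transform each feature.

    The imputation exists strictly to make PCA possible; it is never
    written back to the data. Features that are all-missing or have zero
    variance after imputation are dropped with a warning.
    """
    ids = list(ids)
    sub = matrix.data[ids]
    all_missing = sub.columns[sub.isna().all(axis=0)]
    if len(all_missing):
        warnings.warn(f"{len(all_missing)} all-missing feature(s) dropped")
        sub = sub.drop(columns=list(all_missing))
    filled = sub.fillna(sub.median(axis=0))
    sd = filled.std(axis=0, ddof=1)
    degenerate = filled.columns[(sd == 0) | sd.isna()]
    if len(degenerate):
        warnings.warn(f"{len(degenerate)} zero-variance feature(s) dropped")
        filled = filled.drop(columns=list(degenerate))
    return (filled - filled.mean(axis=0)) / filled.std(axis=0, ddof=1)


def run_pca(standardized: pd.DataFrame, n_components: int | None = None) -> PcaResult:
    """PCA of the standardized matrix.

    Component signs are fixed so each component's largest-magnitude
    loading is positive, making outputs byte-reproducible.
    """
    n, p = standardized.shape
    if n < 2 or p < 2:
        raise ValueError("PCA requires at least 2 samples and 2 features")
    max_comp = min(n - 1, p)
    if max_comp < 2:
        raise ValueError("fewer than 2 components available")
    n_components = max_comp if n_components is None else min(n_components, max_comp)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(standardized.to_numpy())
    loadings = pca.components_  # (components, features)
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] *= -1.0
            scores[:, i] *= -1.0
    names = [f"PC{i + 1}" for i in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=standardized.index, columns=names),
        eigenvalues=pca.explained_variance_.copy(),
        variance_explained=pca.explained_variance_ratio_.copy(),
        loadings=pd.DataFrame(loadings, index=names, columns=standardized.columns),
    )


def acceleration_factor_n(eigenvalues, min_components: int = 2) -> int:
    """Scree elbow by the maximum second difference of the eigenvalues.

    With eigenvalues e_1 >= e_2 >= ..., the acceleration at interior
    position i is a_i = e_{i+1} - 2 e_i + e_{i-1}; the retained count is
    (argmax_i a_i) - 1, floored at ``min_components``. Ties go to the
    smallest i.
    """
    e = np.asarray(eigenvalues, dtype=float)
    if e.size < 3:
        raise ValueError("acceleration factor needs at least 3 eigenvalues")
    a = e[2:] - 2.0 * e[1:-1] + e[:-2]
    i = int(np.argmax(a)) + 2  # 1-based interior index of the elbow
    return max(i - 1, min_components)


def parallel_analysis_n(
    eigenvalues,
    n_samples: int,
    n_features: int,
    reps: int = 100,
    seed: int = 0,
    centile: float = 95.0,
) -> int:
    """Component retention by comparison with simulated uncorrelated data.

    Simulates ``reps`` standardized standard-normal matrices of the same
    shape and counts how many observed eigenvalues exceed the per-rank
    ``centile`` of the null eigenvalues.
    """
    if reps < 10:
        raise ValueError("parallel analysis needs reps >= 10")
    obs = np.asarray(eigenvalues, dtype=float)
    rng = np.random.default_rng(seed)
    m = min(n_samples - 1, n_features)
    null = np.empty((reps, m))
    for r in range(reps):
        x = rng.standard_normal((n_samples, n_features))
        x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
        s = np.linalg.svd(x - x.mean(axis=0), compute_uv=False)
        null[r] = (s[:m] ** 2) / (n_samples - 1)
    thresh = np.percentile(null, centile, axis=0)
    L = min(obs.size, m)
    return int(np.sum(obs[:L] > thresh[:L]))


def pc_outliers(scores: pd.DataFrame, n_components: int, sd_threshold: float) -> list[str]:
    """Samples beyond ``sd_threshold`` SDs from the mean on any of the
    top ``n_components`` components."""
    n_components = min(n_components, scores.shape[1])
    sub = scores.iloc[:, :n_components]
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=1)
    dev = (sub - mean).abs()
    flagged = (dev > sd_threshold * sd).any(axis=1)
    return list(scores.index[flagged])


def handle_outlier_values(
    matrix: AbundanceMatrix, flags: pd.DataFrame, mode: str = "leave"
) -> AbundanceMatrix:
    """Neutralize flagged extreme cells for the PCA working copy only.

    ``to_na`` turns flagged cells into missing (to be median-imputed
    downstream); ``winsorize`` replaces each flagged cell with the most
    extreme non-flagged value of that feature on the same side of the
    median; ``leave`` is the identity. Exported data are never modified.
    """
    if mode == "leave":
        return matrix.copy()
    if mode not in ("to_na", "winsorize"):
        raise ValueError(f"unknown outlier mode {mode!r}")
    df = matrix.data.copy()
    flags = flags.reindex(index=df.index, columns=df.columns).fillna(False)
    if mode == "to_na":
        return AbundanceMatrix(df.mask(flags))
    med = df.median(axis=0)
    for col in df.columns:
        col_flags = flags[col]
        if not col_flags.any():
            continue
        ok = df[col][~col_flags].dropna()
        if ok.empty:
            continue
        hi, lo = ok.max(), ok.min()
        above = col_flags & (df[col] >= med[col])
        below = col_flags & (df[col] < med[col])
        df.loc[above, col] = hi
        df.loc[below, col] = lo
    return AbundanceMatrix(df)
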