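"""Seeded synthetic metabolomics datasets with known ground truth.

The generator emulates the data properties the pipeline is built for:
right-skewed (log-normal) feature abundances, block-correlated feature
clusters, multiplicative batch median shifts, feature- and sample-level
missingness, presence/absence xenobiotic features, derived features as
ratios of parents (so parent missingness propagates), planted extreme
cells and planted outlier samples of two kinds — a whole-profile
abundance shift (caught by the TSA filter) and a correlated shift on
one feature block (caught by the PC filter).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import AbundanceMatrix, FeatureAnnotation, SampleMetadata
from .io import write_matrix

__all__ = ["FixtureTruth", "generate_fixture", "write_fixture"]

HIGH_MISSING_FRACTION = 0.85  # planted missingness of designated bad samples
TSA_SHIFT_FACTOR = 10.0  # whole-profile multiplicative shift
PC_SHIFT_SD = 10.0  # additive shift in feature-SD units on one block
OUTLIER_CELL_IQR = 7.0  # planted cells sit 7 IQRs above the median


@dataclass
class FixtureTruth:
    """Ground truth planted by :func:`generate_fixture`."""

    block_of_feature: pd.Series
    batch_factors: pd.DataFrame  # features x batches multiplicative shifts
    missing_mask: pd.DataFrame  # True where a cell was planted missing
    outlier_cells: list[tuple[str, str]]
    tsa_outlier_samples: list[str]
    pc_outlier_samples: list[str]
    high_missing_samples: list[str]
    xenobiotic_ids: list[str]
    derived_ids: list[str]
    complete_feature_ids: list[str]
    pc_shift_features: list[str] = field(default_factory=list)


def generate_fixture(
    n_samples: int = 200,
    n_features: int = 60,
    n_blocks: int = 3,
    within_block_rho: float = 0.9,
    batch_count: int = 2,
    batch_shift: float = 0.15,
    feature_missing_rate: float = 0.05,
    n_high_missing_samples: int = 0,
    n_outlier_cells: int = 10,
    n_tsa_outlier_samples: int = 1,
    n_pc_outlier_samples: int = 1,
    n_xenobiotics: int = 4,
    n_derived: int = 4,
    seed: int = 1,
) -> tuple[AbundanceMatrix, SampleMetadata, FeatureAnnotation, FixtureTruth]:
    """Generate a seeded dataset with planted structure.

    ``n_features`` counts all features; the last ``n_xenobiotics`` +
    ``n_derived`` are xenobiotics / derived ratios, the remaining core
    features are assigned round-robin to ``n_blocks`` correlation
    blocks. Half of the core features are fully observed; the other
    half receive Bernoulli cell missingness at twice
    ``feature_missing_rate`` so the overall planted rate matches the
    request while complete features still exist. Outlier samples:
    ``n_tsa_outlier_samples`` get a whole-profile x10 shift (for the
    TSA filter), ``n_pc_outlier_samples`` get +10 feature-SD additive
    shifts on a few complete features of the first block (for the PC
    filter; the TSA displacement of this pattern stays far below the
    exclusion threshold). ``n_high_missing_samples`` samples have 85%
    of their non-xenobiotic cells blanked.
    """
    n_core = n_features - n_xenobiotics - n_derived
    if n_core < max(n_blocks, 2 * max(n_derived, 1)):
        raise ValueError("too few core features for the requested blocks/derived")
    if not (0 < within_block_rho < 1):
        raise ValueError("within_block_rho must be in (0, 1)")
    if n_high_missing_samples + n_tsa_outlier_samples + n_pc_outlier_samples > n_samples // 4:
        raise ValueError("too many planted special samples")
    rng = np.random.default_rng(seed)

    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    core_ids = [f"met_{j + 1:03d}" for j in range(n_core)]
    xeno_ids = [f"xeno_{j + 1}" for j in range(n_xenobiotics)]
    derived_ids = [f"ratio_{j + 1}" for j in range(n_derived)]
    feature_ids = core_ids + xeno_ids + derived_ids

    # block-correlated latent Gaussians -> log-normal abundances
    blocks = np.arange(n_core) % n_blocks
    factors = rng.standard_normal((n_samples, n_blocks))
    eps = rng.standard_normal((n_samples, n_core))
    g = np.sqrt(within_block_rho) * factors[:, blocks] + np.sqrt(
        1 - within_block_rho
    ) * eps
    mu = rng.uniform(1.0, 3.0, size=n_core)
    sigma = rng.uniform(0.2, 0.45, size=n_core)
    core = np.exp(mu + sigma * g)

    # multiplicative batch median shifts
    batch_labels = np.array([f"B{i % batch_count + 1}" for i in range(n_samples)])
    batch_names = [f"B{b + 1}" for b in range(batch_count)]
    fac = 1.0 + batch_shift * rng.uniform(-1.0, 1.0, size=(n_core, batch_count))
    for b, bname in enumerate(batch_names):
        core[batch_labels == bname] *= fac[:, b]

    df = pd.DataFrame(core, index=sample_ids, columns=core_ids)

    # choose the planted special samples up front, all distinct
    n_special = n_high_missing_samples + n_tsa_outlier_samples + n_pc_outlier_samples
    special = list(rng.choice(n_samples, size=n_special, replace=False))
    high_missing = [sample_ids[i] for i in special[:n_high_missing_samples]]
    tsa_out = [
        sample_ids[i]
        for i in special[n_high_missing_samples : n_high_missing_samples + n_tsa_outlier_samples]
    ]
    pc_out = [sample_ids[i] for i in special[n_high_missing_samples + n_tsa_outlier_samples :]]

    # cell missingness on half of the core features, at 2x the overall rate
    missing_feats = sorted(
        rng.choice(n_core, size=n_core // 2, replace=False).tolist()
    )
    mask = np.zeros((n_samples, n_core), dtype=bool)
    if feature_missing_rate > 0:
        cell_rate = min(2.0 * feature_missing_rate, 1.0)
        mask[:, missing_feats] = rng.random((n_samples, len(missing_feats))) < cell_rate
    complete_core = [core_ids[j] for j in range(n_core) if j not in missing_feats]

    # planted extreme cells: in missing-type core features only, ordinary samples
    ordinary = [i for i, s in enumerate(sample_ids) if s not in set(high_missing + tsa_out + pc_out)]
    outlier_cells: list[tuple[str, str]] = []
    for _ in range(n_outlier_cells):
        j = int(rng.choice(missing_feats)) if missing_feats else int(rng.integers(n_core))
        i = int(rng.choice(ordinary))
        col = df.iloc[:, j]
        med = float(col.median())
        iqr = float(col.quantile(0.75) - col.quantile(0.25))
        df.iloc[i, j] = med + OUTLIER_CELL_IQR * max(iqr, 1e-6)
        mask[i, j] = False
        outlier_cells.append((sample_ids[i], core_ids[j]))

    # TSA outlier samples: whole-profile multiplicative shift
    for s in tsa_out:
        df.loc[s] = df.loc[s] * TSA_SHIFT_FACTOR

    # PC outlier samples: +10 SD on a few complete features of block 0,
    # including that block's representative (its first complete feature)
    block0_complete = [f for f in complete_core if blocks[core_ids.index(f)] == 0]
    pc_shift_feats = block0_complete[: min(4, len(block0_complete))]
    for s in pc_out:
        for f in pc_shift_feats:
            df.loc[s, f] += PC_SHIFT_SD * float(df[f].std(ddof=1))

    # xenobiotics: presence/absence, high missingness
    xeno = pd.DataFrame(np.nan, index=sample_ids, columns=xeno_ids)
    for col in xeno_ids:
        present = rng.random(n_samples) < 0.15
        xeno.loc[present, col] = np.exp(1.0 + 0.5 * rng.standard_normal(int(present.sum())))

    # apply core missingness, then derived ratios so parent NAs propagate
    core_masked = df.where(~mask)
    derived = pd.DataFrame(index=sample_ids, columns=derived_ids, dtype=float)
    parents: dict[str, tuple[str, str]] = {}
    for j, col in enumerate(derived_ids):
        pa = complete_core[j % len(complete_core)]
        pb = core_ids[missing_feats[j % len(missing_feats)]] if missing_feats else complete_core[-1 - j]
        parents[col] = (pa, pb)
        derived[col] = core_masked[pa] / core_masked[pb]

    full = pd.concat([core_masked, xeno, derived], axis=1)

    # designated high-missingness samples: blank an exact 85% of their
    # non-xenobiotic cells
    non_xeno = core_ids + derived_ids
    n_blank = int(np.ceil(HIGH_MISSING_FRACTION * len(non_xeno)))
    for s in high_missing:
        cols = rng.choice(len(non_xeno), size=n_blank, replace=False)
        full.loc[s, [non_xeno[c] for c in cols]] = np.nan

    full.index.name = "sample_id"
    matrix = AbundanceMatrix(full)

    meta = SampleMetadata(
        pd.DataFrame(
            {
                "batch": batch_labels,
                "run_day": [f"day{(i // max(n_samples // 4, 1)) + 1}" for i in range(n_samples)],
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    ann = FeatureAnnotation(
        pd.DataFrame(
            {
                "is_xenobiotic": [f in set(xeno_ids) for f in feature_ids],
                "is_derived": [f in set(derived_ids) for f in feature_ids],
            },
            index=pd.Index(feature_ids, name="feature_id"),
        )
    )
    truth = FixtureTruth(
        block_of_feature=pd.Series(blocks, index=core_ids, name="block"),
        batch_factors=pd.DataFrame(fac, index=core_ids, columns=batch_names),
        missing_mask=full.isna(),
        outlier_cells=outlier_cells,
        tsa_outlier_samples=tsa_out,
        pc_outlier_samples=pc_out,
        high_missing_samples=high_missing,
        xenobiotic_ids=xeno_ids,
        derived_ids=derived_ids,
        complete_feature_ids=complete_core,
        pc_shift_features=pc_shift_feats,
    )
    return matrix, meta, ann, truth


def write_fixture(outdir, seed: int = 1, **kwargs) -> dict[str, Path]:
    """Generate a fixture and write it in the formats the readers accept."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, meta, ann, _ = generate_fixture(seed=seed, **kwargs)
    paths = {
        "matrix": outdir / "abundance_matrix.tsv",
        "sample_metadata": outdir / "sample_metadata.tsv",
        "feature_annotation": outdir / "feature_annotation.tsv",
    }
    write_matrix(matrix, paths["matrix"])
    meta.data.to_csv(paths["sample_metadata"], sep="\t")
    out_ann = ann.data.copy()
    for col in ("is_xenobiotic", "is_derived"):
        out_ann[col] = out_ann[col].map({True: "TRUE", False: "FALSE"})
    out_ann.to_csv(paths["feature_annotation"], sep="\t")
    return paths
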