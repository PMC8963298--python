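"""Median batch normalization across platform batches.

Each feature is scaled multiplicatively within each batch so that every
batch's within-batch median equals the feature's overall (pre-scaling)
median. Scaling to the overall median rather than to 1 preserves the
abundance scale used by TSA.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import AbundanceMatrix, SampleMetadata

__all__ = ["median_batch_normalize"]


def median_batch_normalize(
    matrix: AbundanceMatrix,
    meta: SampleMetadata,
    batch_column: str,
) -> AbundanceMatrix:
    """Return a matrix whose within-batch feature medians are equalized.

    Batch-feature pairs with no non-missing values or a zero batch
    median are left unscaled with a warning. A missing batch label is an
    error.
    """
    mdf = meta.aligned(matrix.sample_ids)
    if batch_column not in mdf.columns:
        raise ValueError(f"batch column {batch_column!r} not in sample metadata")
    labels = mdf[batch_column].astype(str)
    blank = labels.str.strip().isin(("", "NA", "NaN"))
    if blank.any():
        raise ValueError(
            f"missing batch label for sample(s) {list(labels.index[blank])[:5]}"
        )

    df = matrix.data
    overall = df.median(axis=0)
    batch_median = df.groupby(labels.to_numpy(), sort=False).transform("median")
    factor = overall / batch_median
    # undefined or zero batch medians, or undefined overall medians: leave unscaled
    bad = ~np.isfinite(factor.to_numpy())
    if bad.any():
        n_pairs = (
            pd.DataFrame(bad, index=df.index, columns=df.columns)
            .groupby(labels.to_numpy(), sort=False)
            .any()
            .to_numpy()
            .sum()
        )
        warnings.warn(
            f"{n_pairs} batch-feature pair(s) left unscaled "
            "(zero or undefined batch median)"
        )
        factor = factor.where(np.isfinite(factor), 1.0)
    return AbundanceMatrix(df * factor)
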