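"""Core in-memory containers for the QC pipeline.

All tabular data are held as pandas objects: the abundance matrix as a
samples x features float frame (``NaN`` = missing), metadata and
annotation as frames indexed by the corresponding identifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceMatrix",
    "SampleMetadata",
    "FeatureAnnotation",
    "ExclusionStep",
    "ExclusionLog",
]


def _check_unique(ids, kind: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = sorted(set(idx[idx.duplicated()]))
        raise ValueError(f"duplicate {kind} identifiers: {dups}")


@dataclass
class AbundanceMatrix:
    """Samples x features matrix of non-negative abundances.

    Parameters
    ----------
    data
        Float DataFrame with sample identifiers as the index and feature
        identifiers as the columns. Missing measurements are ``NaN``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        self.data = self.data.astype(float)
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "feature")
        vals = self.data.to_numpy()
        finite = np.isfinite(vals)
        bad_inf = ~finite & ~np.isnan(vals)
        if bad_inf.any():
            raise ValueError("abundance matrix contains non-finite values")
        if np.nanmin(vals, initial=0.0) < 0:
            i, j = np.argwhere((vals < 0) & finite)[0]
            raise ValueError(
                f"negative abundance at sample {self.data.index[i]!r}, "
                f"feature {self.data.columns[j]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.data.copy())


@dataclass
class SampleMetadata:
    """Per-sample metadata (batch variables such as run day or storage box)."""

    data: pd.DataFrame  # indexed by sample id; columns are variables

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample (metadata)")
        _check_unique(self.data.columns, "metadata variable")

    def aligned(self, sample_ids) -> pd.DataFrame:
        """Return rows for ``sample_ids`` in order; warn about extras."""
        extra = self.data.index.difference(sample_ids)
        if len(extra):
            warnings.warn(
                f"{len(extra)} metadata rows have no matching sample and are ignored"
            )
        missing = pd.Index(sample_ids).difference(self.data.index)
        if len(missing):
            raise ValueError(f"samples without metadata rows: {sorted(missing)[:5]}")
        return self.data.loc[list(sample_ids)]


@dataclass
class FeatureAnnotation:
    """Per-feature class flags that drive exemption rules.

    ``is_xenobiotic`` marks exogenous compounds whose missingness usually
    means true non-exposure; they are exempt from missingness filters.
    ``is_derived`` marks features computed from others (ratios, sums).
    """

    data: pd.DataFrame  # indexed by feature id; columns is_xenobiotic, is_derived, [pathway]

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "feature (annotation)")
        for col in ("is_xenobiotic", "is_derived"):
            if col not in self.data.columns:
                self.data[col] = False
            self.data[col] = self.data[col].astype(bool)

    @classmethod
    def empty(cls, feature_ids) -> "FeatureAnnotation":
        """All-false annotation for matrices without a feature-metadata file."""
        return cls(
            pd.DataFrame(
                {"is_xenobiotic": False, "is_derived": False},
                index=pd.Index(feature_ids, name="feature_id"),
            )
        )

    def aligned(self, feature_ids) -> "FeatureAnnotation":
        """Annotation reindexed to ``feature_ids``; absent features get all-false flags."""
        df = self.data.reindex(feature_ids)
        df["is_xenobiotic"] = df["is_xenobiotic"].fillna(False).astype(bool)
        df["is_derived"] = df["is_derived"].fillna(False).astype(bool)
        return FeatureAnnotation(df)

    def xenobiotic_ids(self) -> list[str]:
        return list(self.data.index[self.data["is_xenobiotic"]])

    def derived_ids(self) -> list[str]:
        return list(self.data.index[self.data["is_derived"]])


@dataclass
class ExclusionStep:
    name: str
    entity: str  # "sample" | "feature"
    threshold: str
    removed_ids: list[str]
    n_before: int
    n_after: int

    def __post_init__(self) -> None:
        if self.entity not in ("sample", "feature"):
            raise ValueError(f"unknown entity kind {self.entity!r}")
        if self.n_before - len(self.removed_ids) != self.n_after:
            raise ValueError(
                f"inconsistent counts in step {self.name!r}: "
                f"{self.n_before} - {len(self.removed_ids)} != {self.n_after}"
            )


@dataclass
class ExclusionLog:
    """Ordered record of the filtering pipeline."""

    steps: list[ExclusionStep] = field(default_factory=list)

    def add(self, **kwargs) -> ExclusionStep:
        step = ExclusionStep(**kwargs)
        self.steps.append(step)
        return step

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "step": i + 1,
                "name": s.name,
                "entity": s.entity,
                "threshold": s.threshold,
                "n_before": s.n_before,
                "n_removed": len(s.removed_ids),
                "n_after": s.n_after,
                "removed_ids": ";".join(s.removed_ids),
            }
            for i, s in enumerate(self.steps)
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "step",
                "name",
                "entity",
                "threshold",
                "n_before",
                "n_removed",
                "n_after",
                "removed_ids",
            ],
        )

    def removed(self, entity: str) -> list[str]:
        out: list[str] = []
        for s in self.steps:
            if s.entity == entity:
                out.extend(s.removed_ids)
        return out
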