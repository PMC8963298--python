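"""Readers and writers for the pipeline's plain-text artifacts.

All tables are tab-delimited (``.txt``/``.tsv``) or comma-delimited
(``.csv``), sniffed by extension. Missing values are written as ``NA``
and recognized on input as one of the case-sensitive tokens
``{"NA", "", "NaN"}``. Floats are written with 12 significant digits so
repeated runs diff cleanly.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import AbundanceMatrix, ExclusionLog, FeatureAnnotation, SampleMetadata

__all__ = [
    "MISSING_TOKENS",
    "read_matrix",
    "read_sample_metadata",
    "read_feature_annotation",
    "write_matrix",
    "write_tables",
]

MISSING_TOKENS = ("NA", "", "NaN")
FLOAT_FORMAT = "%.12g"


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_cells(path: Path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep=_sep_for(path),
        header=None,
        dtype=str,
        keep_default_na=False,
        na_values=[],
        skip_blank_lines=True,
    )


def read_matrix(
    path,
    orientation: str = "samples_in_rows",
    known_sample_ids=None,
) -> AbundanceMatrix:
    """Read an abundance matrix from delimited text.

    Parameters
    ----------
    path
        ``.txt``/``.tsv`` (tab) or ``.csv`` (comma) file whose first row
        and column hold identifiers.
    orientation
        ``"samples_in_rows"`` or ``"features_in_rows"``. Pass ``None``
        to auto-detect against ``known_sample_ids`` (an explicit flag is
        otherwise required; silent transposition is a classic failure
        mode).
    """
    path = Path(path)
    raw = _read_cells(path)
    row_ids = [str(x) for x in raw.iloc[1:, 0]]
    col_ids = [str(x) for x in raw.iloc[0, 1:]]
    cells = raw.iloc[1:, 1:].to_numpy(dtype=object)

    if orientation is None:
        if known_sample_ids is None:
            raise ValueError("orientation is required when no sample ids are known")
        known = set(map(str, known_sample_ids))
        rows_match = len(known.intersection(row_ids)) > len(known.intersection(col_ids))
        orientation = "samples_in_rows" if rows_match else "features_in_rows"
    if orientation not in ("samples_in_rows", "features_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")

    missing = np.isin(cells.astype(str), MISSING_TOKENS)
    flat = pd.Series(cells.ravel(), dtype=object).where(~missing.ravel(), np.nan)
    numeric = pd.to_numeric(flat, errors="coerce").to_numpy().reshape(cells.shape)
    bad = np.isnan(numeric) & ~missing
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-numeric cell {cells[i, j]!r} at row {row_ids[i]!r}, "
            f"column {col_ids[j]!r} in {path}"
        )
    neg = numeric < 0
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise ValueError(
            f"negative value {numeric[i, j]} at row {row_ids[i]!r}, "
            f"column {col_ids[j]!r} in {path}"
        )

    df = pd.DataFrame(numeric, index=row_ids, columns=col_ids)
    if orientation == "features_in_rows":
        df = df.T
    df.index.name = "sample_id"
    df.columns.name = None
    return AbundanceMatrix(df)


def read_sample_metadata(path) -> SampleMetadata:
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=_sep_for(path),
        index_col=0,
        dtype=str,
        keep_default_na=False,
        na_values=[],
    )
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    return SampleMetadata(df)


_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""} | {t.lower() for t in MISSING_TOKENS}


def _parse_flag(col: pd.Series, name: str) -> pd.Series:
    low = col.astype(str).str.strip().str.lower()
    ok = low.isin(_TRUE | _FALSE)
    if not ok.all():
        bad = col[~ok].iloc[0]
        raise ValueError(f"cannot parse {name} value {bad!r} as boolean")
    return low.isin(_TRUE)


def read_feature_annotation(path) -> FeatureAnnotation:
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=_sep_for(path),
        index_col=0,
        dtype=str,
        keep_default_na=False,
        na_values=[],
    )
    df.index = df.index.astype(str)
    df.index.name = "feature_id"
    out = pd.DataFrame(index=df.index)
    for col in ("is_xenobiotic", "is_derived"):
        out[col] = _parse_flag(df[col], col) if col in df.columns else False
    if "pathway" in df.columns:
        out["pathway"] = df["pathway"]
    return FeatureAnnotation(out)


def write_matrix(matrix: AbundanceMatrix, path) -> None:
    path = Path(path)
    matrix.data.to_csv(
        path, sep=_sep_for(path), na_rep="NA", float_format=FLOAT_FORMAT
    )


def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", float_format=FLOAT_FORMAT)


def write_tables(
    outdir,
    *,
    raw_matrix: AbundanceMatrix,
    filtered_matrix: AbundanceMatrix,
    raw_sample_summary: pd.DataFrame,
    raw_feature_summary: pd.DataFrame,
    filtered_sample_summary: pd.DataFrame,
    filtered_feature_summary: pd.DataFrame,
    exclusion_log: ExclusionLog,
    run_log_lines: list[str] | None = None,
) -> dict[str, Path]:
    """Write the fixed set of pipeline output files into ``outdir``.

    Returns a mapping of artifact name to written path. Outputs are
    byte-identical across reruns with identical inputs and seed (no
    timestamps are written).
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {outdir} is not writable: {exc}") from exc

    paths = {
        "raw_matrix": outdir / "raw_matrix.tsv",
        "filtered_matrix": outdir / "filtered_matrix.tsv",
        "raw_sample_summary": outdir / "raw_sample_summary.tsv",
        "raw_feature_summary": outdir / "raw_feature_summary.tsv",
        "filtered_sample_summary": outdir / "filtered_sample_summary.tsv",
        "filtered_feature_summary": outdir / "filtered_feature_summary.tsv",
        "exclusion_log": outdir / "exclusion_log.tsv",
        "run_log": outdir / "run_log.txt",
    }
    write_matrix(raw_matrix, paths["raw_matrix"])
    write_matrix(filtered_matrix, paths["filtered_matrix"])
    _write_table(raw_sample_summary, paths["raw_sample_summary"])
    _write_table(raw_feature_summary, paths["raw_feature_summary"])
    _write_table(filtered_sample_summary, paths["filtered_sample_summary"])
    _write_table(filtered_feature_summary, paths["filtered_feature_summary"])
    exclusion_log.to_frame().to_csv(paths["exclusion_log"], sep="\t", index=False)
    lines = run_log_lines or [
        f"{s.name}: removed {len(s.removed_ids)} {s.entity}(s) at {s.threshold}"
        for s in exclusion_log.steps
    ]
    paths["run_log"].write_text("\n".join(lines) + "\n")
    return paths
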