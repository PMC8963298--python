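"""Self-contained HTML QC report and per-feature plot document.

Pure presentation: every number shown is taken from the summary tables
and results computed upstream; nothing is recomputed here. Figures are
embedded as base64 PNGs so the report is a single portable file.
"""

from __future__ import annotations

import base64
import io as _io
import warnings
from dataclasses import fields
from html import escape
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.backends.backend_pdf import PdfPages
from scipy.cluster.hierarchy import dendrogram
from sklearn.cluster import KMeans

from .config import PipelineConfig
from .datatypes import AbundanceMatrix, ExclusionLog

__all__ = ["render_report", "render_feature_document", "SECTION_ANCHORS"]

SECTION_ANCHORS = (
    "overview",
    "missingness-matrix",
    "missingness-distributions",
    "exclusion-summary",
    "dendrogram",
    "scree",
    "pc-scatter",
    "tsa",
    "shapiro",
    "outliers",
    "batch-effects",
    "power",
    "config-echo",
)

_PLACEHOLDER = "<p class='placeholder'>not available</p>"


def _embed(fig) -> str:
    buf = _io.BytesIO()
    fig.savefig(buf, format="png", dpi=100)
    plt.close(fig)
    data = base64.b64encode(buf.getvalue()).decode("ascii")
    return f'<img src="data:image/png;base64,{data}"/>'


def _table(df: pd.DataFrame, max_rows: int = 30) -> str:
    if df is None or len(df) == 0:
        return _PLACEHOLDER
    shown = df.head(max_rows)
    head = "".join(f"<th>{escape(str(c))}</th>" for c in shown.columns)
    body = []
    for _, row in shown.iterrows():
        cells = "".join(
            f"<td>{escape(f'{v:.4g}') if isinstance(v, float) else escape(str(v))}</td>"
            for v in row
        )
        body.append(f"<tr>{cells}</tr>")
    note = f"<p>showing {len(shown)} of {len(df)} rows</p>" if len(df) > max_rows else ""
    return f"<table><tr>{head}</tr>{''.join(body)}</table>{note}"


def _hist(series, title, xlabel, bins=30):
    fig, ax = plt.subplots(figsize=(5, 3))
    vals = pd.Series(series).dropna()
    if len(vals):
        ax.hist(vals, bins=bins, color="#4878a8", edgecolor="white")
    ax.set_title(title, fontsize=10)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("count")
    fig.tight_layout()
    return fig


def _missingness_matrix_fig(matrix: AbundanceMatrix):
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.imshow(matrix.data.isna().to_numpy(), aspect="auto", cmap="Greys",
              interpolation="nearest")
    ax.set_xlabel("features")
    ax.set_ylabel("samples")
    ax.set_title("missing-data pattern (black = missing)", fontsize=10)
    fig.tight_layout()
    return fig


def _dendrogram_fig(clustering, cut_height):
    fig, ax = plt.subplots(figsize=(7, 3.5))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dendrogram(
            clustering.linkage_matrix,
            labels=clustering.feature_ids,
            ax=ax,
            color_threshold=cut_height,
            no_labels=len(clustering.feature_ids) > 40,
        )
    ax.axhline(cut_height, color="red", linestyle="--", linewidth=1)
    reps = ", ".join(clustering.representatives[:12])
    more = "..." if len(clustering.representatives) > 12 else ""
    ax.set_title(
        f"feature dendrogram (k={clustering.k}); representatives: {reps}{more}",
        fontsize=9,
    )
    ax.set_ylabel("1 - |Spearman rho|")
    fig.tight_layout()
    return fig


def _scree_fig(pca):
    fig, ax = plt.subplots(figsize=(5.5, 3.5))
    ve = pca.variance_explained
    ax.plot(np.arange(1, len(ve) + 1), ve, "o-", color="#4878a8", markersize=3)
    if pca.n_accel is not None:
        ax.axvline(pca.n_accel, color="red", linestyle="--", linewidth=1,
                   label=f"acceleration factor n={pca.n_accel}")
    if pca.n_parallel is not None:
        ax.axvline(pca.n_parallel, color="green", linestyle=":", linewidth=1,
                   label=f"parallel analysis n={pca.n_parallel}")
    ax.set_xlabel("component")
    ax.set_ylabel("variance explained")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def _pc_scatter_fig(pca, seed: int):
    scores = pca.scores
    fig, ax = plt.subplots(figsize=(5, 4.2))
    x = scores.iloc[:, 0]
    y = scores.iloc[:, 1] if scores.shape[1] > 1 else x * 0
    if len(scores) >= 4:
        # cosmetic k-means coloring of the top two PCs
        km = KMeans(n_clusters=4, n_init=10, random_state=seed)
        col = km.fit_predict(np.column_stack([x, y]))
    else:
        col = np.zeros(len(scores))
    ax.scatter(x, y, c=col, cmap="tab10", s=12)
    out = set(pca.outlier_sample_ids)
    if out:
        sel = scores.index.isin(out)
        ax.scatter(x[sel], y[sel], facecolors="none", edgecolors="red", s=60,
                   label="PC outlier")
        ax.legend(fontsize=8)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_title("sample structure (k-means coloring is cosmetic)", fontsize=9)
    fig.tight_layout()
    return fig


def _power_fig(curves):
    fig, axes = plt.subplots(1, len(curves), figsize=(5 * len(curves), 3.2))
    axes = np.atleast_1d(axes)
    for ax, pc in zip(axes, curves):
        for i, n in enumerate(pc.n_grid):
            ax.plot(pc.effect_grid, pc.power[:, i], "o-", markersize=3,
                    label=f"n={n}")
        ax.set_xlabel("Cohen's d" if pc.kind == "binary" else "Cohen's f$^2$")
        ax.set_ylabel("power")
        ax.set_title(f"{pc.kind} trait (alpha={pc.alpha})", fontsize=9)
        ax.legend(fontsize=7)
    fig.tight_layout()
    return fig


def _batch_fig(sample_summary, metadata, batch_table):
    if batch_table is None or len(batch_table) == 0:
        return None
    pairs = list(
        batch_table[["outcome", "variable"]].drop_duplicates().itertuples(index=False)
    )[:4]
    fig, axes = plt.subplots(1, len(pairs), figsize=(4 * len(pairs), 3.2))
    axes = np.atleast_1d(axes)
    for ax, (outcome, var) in zip(axes, pairs):
        df = pd.DataFrame(
            {"y": sample_summary[outcome], "g": metadata[var].reindex(sample_summary.index)}
        ).dropna()
        groups = [g["y"].to_numpy() for _, g in df.groupby("g")]
        names = [str(k) for k, _ in df.groupby("g")]
        ax.boxplot(groups, tick_labels=names)
        row = batch_table[
            (batch_table["outcome"] == outcome) & (batch_table["variable"] == var)
        ].iloc[0]
        ax.set_title(
            f"{outcome} ~ {var}\n" + r"$\eta^2$" + f" = {row['eta2_univariate']:.3f}",
            fontsize=9,
        )
        ax.tick_params(axis="x", rotation=45, labelsize=7)
    fig.tight_layout()
    return fig


def render_report(
    outpath,
    *,
    config: PipelineConfig,
    raw_matrix: AbundanceMatrix | None = None,
    raw_sample_summary: pd.DataFrame | None = None,
    raw_feature_summary: pd.DataFrame | None = None,
    filtered_sample_summary: pd.DataFrame | None = None,
    filtered_feature_summary: pd.DataFrame | None = None,
    clustering=None,
    pca=None,
    exclusion_log: ExclusionLog | None = None,
    batch_table: pd.DataFrame | None = None,
    batch_notes: list[str] | None = None,
    sample_metadata: pd.DataFrame | None = None,
    power_curves=None,
    project: str = "metaboqc run",
    platform: str = "unspecified",
) -> Path:
    """Render the standardized single-file HTML report.

    Any missing component renders as a "not available" placeholder.
    """
    S: dict[str, str] = {a: _PLACEHOLDER for a in SECTION_ANCHORS}

    if raw_matrix is not None:
        n_filt_s = len(filtered_sample_summary) if filtered_sample_summary is not None else "?"
        n_filt_f = len(filtered_feature_summary) if filtered_feature_summary is not None else "?"
        S["overview"] = (
            f"<p>Project: <b>{escape(project)}</b> | platform: {escape(platform)}</p>"
            f"<p>Raw dataset: {raw_matrix.n_samples} samples x "
            f"{raw_matrix.n_features} features. Filtered dataset: "
            f"{n_filt_s} samples x {n_filt_f} features.</p>"
        )
        S["missingness-matrix"] = _embed(_missingness_matrix_fig(raw_matrix))

    if raw_sample_summary is not None and raw_feature_summary is not None:
        f1 = _hist(raw_sample_summary["missingness_excl"],
                   "sample missingness", "fraction missing")
        f2 = _hist(raw_feature_summary["missingness"],
                   "feature missingness", "fraction missing")
        S["missingness-distributions"] = _embed(f1) + _embed(f2)
        S["shapiro"] = _embed(
            _hist(raw_feature_summary["w_raw"], "Shapiro W (raw)", "W")
        ) + _embed(
            _hist(raw_feature_summary["w_log10"], "Shapiro W (log10)", "W")
        )
        S["outliers"] = (
            "<h4>per-sample extreme-value counts</h4>"
            + _embed(_hist(raw_sample_summary["outlier_count"],
                           "outlying cells per sample", "count"))
            + "<h4>per-feature extreme-value counts</h4>"
            + _embed(_hist(raw_feature_summary["outlier_count"],
                           "outlying cells per feature", "count"))
        )

    src = filtered_sample_summary if filtered_sample_summary is not None else raw_sample_summary
    if src is not None:
        S["tsa"] = _embed(
            _hist(src["tsa_complete"], "TSA over complete features", "TSA")
        )

    if exclusion_log is not None:
        S["exclusion-summary"] = _table(exclusion_log.to_frame().drop(columns="removed_ids"))
    if clustering is not None:
        S["dendrogram"] = _embed(_dendrogram_fig(clustering, config.tree_cut_height))
    if pca is not None:
        S["scree"] = _embed(_scree_fig(pca))
        if pca.scores.shape[1] >= 2:
            S["pc-scatter"] = _embed(_pc_scatter_fig(pca, config.rng_seed))
    if batch_table is not None and len(batch_table):
        notes = "".join(f"<p>{escape(n)}</p>" for n in (batch_notes or []))
        fig = _batch_fig(src, sample_metadata, batch_table)
        S["batch-effects"] = _table(batch_table) + (_embed(fig) if fig else "") + notes
    elif batch_notes:
        S["batch-effects"] = "".join(f"<p>{escape(n)}</p>" for n in batch_notes)
    if power_curves:
        S["power"] = _embed(_power_fig(power_curves))

    cfg_rows = "".join(
        f"<tr><td>{f.name}</td><td>{escape(str(getattr(config, f.name)))}</td></tr>"
        for f in fields(config)
    )
    S["config-echo"] = f"<table><tr><th>parameter</th><th>value</th></tr>{cfg_rows}</table>"

    titles = {
        "overview": "Overview",
        "missingness-matrix": "Missing-data matrix",
        "missingness-distributions": "Missingness distributions",
        "exclusion-summary": "Exclusion summary",
        "dendrogram": "Feature dendrogram and representatives",
        "scree": "Scree plot and retained components",
        "pc-scatter": "Principal-component plot",
        "tsa": "Total sum abundance",
        "shapiro": "Normality (Shapiro W)",
        "outliers": "Extreme-value summaries",
        "batch-effects": "Batch effects",
        "power": "Power analysis",
        "config-echo": "Parameters",
    }
    body = "".join(
        f'<section id="{a}"><h2>{titles[a]}</h2>{S[a]}</section>'
        for a in SECTION_ANCHORS
    )
    html = (
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        f"<title>{escape(project)} QC report</title>"
        "<style>body{font-family:sans-serif;margin:2em;max-width:1100px}"
        "table{border-collapse:collapse}td,th{border:1px solid #999;"
        "padding:3px 8px;font-size:12px}img{max-width:100%}"
        ".placeholder{color:#888;font-style:italic}</style></head><body>"
        f"<h1>{escape(project)} — metabolomics QC report</h1>{body}</body></html>"
    )
    outpath = Path(outpath)
    outpath.write_text(html)
    return outpath


def render_feature_document(
    matrix: AbundanceMatrix,
    feature_summary: pd.DataFrame,
    flags: pd.DataFrame,
    outpath,
    max_features: int | None = None,
) -> Path:
    """Write a multipage PDF: one page per feature with an index-ordered
    scatter (outlying points marked), a histogram, and a statistics inset."""
    outpath = Path(outpath)
    cols = list(matrix.data.columns)
    if max_features is not None:
        cols = cols[:max_features]
    with PdfPages(outpath, metadata={"CreationDate": None}) as pdf:
        for col in cols:
            vals = matrix.data[col]
            fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3.2))
            if vals.notna().any():
                idx = np.arange(len(vals))
                ok = vals.notna().to_numpy()
                fl = flags[col].reindex(vals.index).fillna(False).to_numpy() if col in flags else np.zeros(len(vals), bool)
                ax1.scatter(idx[ok & ~fl], vals[ok & ~fl], s=8, color="#4878a8")
                if (ok & fl).any():
                    ax1.scatter(idx[ok & fl], vals[ok & fl], s=20, color="red",
                                label="outlier")
                    ax1.legend(fontsize=7)
                ax2.hist(vals.dropna(), bins=25, color="#4878a8", edgecolor="white")
            else:
                ax1.text(0.5, 0.5, "all values missing", ha="center", va="center",
                         transform=ax1.transAxes)
            ax1.set_title(str(col), fontsize=10)
            ax1.set_xlabel("sample index")
            ax2.set_xlabel("abundance")
            row = feature_summary.loc[col] if col in feature_summary.index else None
            if row is not None:
                txt = (
                    f"n={row['n']:.0f}  miss={row['missingness']:.3f}\n"
                    f"mean={row['mean']:.4g}  sd={row['sd']:.4g}\n"
                    f"skew={row['skew']:.3g}  W={row['w_raw']:.3f}\n"
                    f"W(log10)={row['w_log10']:.3f}  outliers={row['outlier_count']:.0f}"
                )
                ax2.text(0.98, 0.95, txt, transform=ax2.transAxes, fontsize=7,
                         va="top", ha="right",
                         bbox=dict(boxstyle="round", fc="white", ec="#999"))
            fig.tight_layout()
            pdf.savefig(fig)
            plt.close(fig)
    return outpath
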