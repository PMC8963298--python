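"""Batch-effect quantification via eta-squared.

Univariate: one-way ANOVA, eta² = SS_between / SS_total. Multi-term:
an additive linear model over all batch variables with type-II sums of
squares, eta² = SS_term / SS_total; terms whose dummy columns are
linearly dependent on the rest of the design are flagged aliased.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["univariate_eta2", "type2_eta2", "batch_effect_table"]


def _clean_pairs(outcome: pd.Series, batch: pd.Series):
    df = pd.DataFrame({"y": pd.to_numeric(outcome, errors="coerce"), "g": batch})
    df["g"] = df["g"].astype(str)
    df = df[df["y"].notna() & ~df["g"].str.strip().isin(("", "NA", "NaN"))]
    return df


def univariate_eta2(outcome: pd.Series, batch: pd.Series) -> float:
    """One-way ANOVA eta-squared of ``outcome`` across ``batch`` groups.

    Returns NaN (flagged undefined) for a constant outcome; fewer than
    two groups is an error.
    """
    df = _clean_pairs(outcome, batch)
    groups = df.groupby("g")["y"]
    if groups.ngroups < 2:
        raise ValueError("eta-squared needs at least 2 batch groups")
    y = df["y"].to_numpy()
    ss_total = float(((y - y.mean()) ** 2).sum())
    if ss_total == 0:
        return np.nan
    ss_between = float(
        (groups.size() * (groups.mean() - y.mean()) ** 2).sum()
    )
    return ss_between / ss_total


def _dummy_block(col: pd.Series) -> np.ndarray:
    d = pd.get_dummies(col.astype(str), drop_first=True, dtype=float)
    return d.to_numpy()


def type2_eta2(outcome: pd.Series, batch_variables: pd.DataFrame) -> pd.DataFrame:
    """Type-II eta-squared per batch term in an additive linear model.

    Samples with a missing outcome or any missing batch value are
    dropped listwise. For each term, SS_term = RSS(model without term)
    - RSS(full model); eta² = SS_term / SS_total. Aliased terms (design
    rank unchanged by the term) get ``aliased=True`` and NaN eta².
    """
    y = pd.to_numeric(outcome, errors="coerce")
    bdf = batch_variables.astype(str)
    keep = y.notna()
    for col in bdf.columns:
        keep &= ~bdf[col].str.strip().isin(("", "NA", "NaN"))
    y = y[keep].to_numpy()
    bdf = bdf.loc[keep]
    n = y.size
    if n < 3:
        raise ValueError("too few complete observations for the batch model")

    blocks = {c: _dummy_block(bdf[c]) for c in bdf.columns}
    intercept = np.ones((n, 1))

    def design(exclude: str | None) -> np.ndarray:
        parts = [intercept] + [b for c, b in blocks.items() if c != exclude]
        return np.hstack(parts)

    def rss(X: np.ndarray) -> float:
        return float(sm.OLS(y, X).fit().ssr)

    X_full = design(None)
    rank_full = np.linalg.matrix_rank(X_full)
    rss_full = rss(X_full)
    ss_total = float(((y - y.mean()) ** 2).sum())

    rows = []
    for term in bdf.columns:
        X_red = design(term)
        aliased = np.linalg.matrix_rank(X_red) == rank_full
        if aliased or ss_total == 0:
            eta2 = np.nan
        else:
            eta2 = max(rss(X_red) - rss_full, 0.0) / ss_total
        rows.append({"term": term, "eta2": eta2, "aliased": aliased})
    return pd.DataFrame(rows)


def batch_effect_table(
    sample_summary: pd.DataFrame,
    metadata: pd.DataFrame,
    outcomes: tuple[str, ...] = ("missingness_excl", "tsa_complete"),
) -> tuple[pd.DataFrame, list[str]]:
    """Eta-squared of every categorical batch variable on each outcome.

    Numeric metadata columns are rejected with a message (continuous
    batch descriptors are not binned). Returns the result table and a
    list of notes.
    """
    notes: list[str] = []
    meta = metadata.reindex(sample_summary.index)
    usable = []
    for col in meta.columns:
        vals = meta[col].astype(str).str.strip()
        nonmiss = vals[~vals.isin(("", "NA", "NaN"))]
        if pd.to_numeric(nonmiss, errors="coerce").notna().all() and nonmiss.nunique() > min(
            20, max(2, len(nonmiss) // 10)
        ):
            notes.append(
                f"variable {col!r} looks continuous and was rejected; "
                "provide categorical batch variables"
            )
            continue
        if nonmiss.nunique() < 2:
            notes.append(f"variable {col!r} has < 2 levels and was skipped")
            continue
        usable.append(col)

    rows = []
    for outcome in outcomes:
        if outcome not in sample_summary.columns:
            continue
        y = sample_summary[outcome]
        multi = None
        if usable:
            try:
                multi = type2_eta2(y, meta[usable]).set_index("term")
            except ValueError as exc:
                notes.append(f"multi-term model for {outcome!r} failed: {exc}")
        for col in usable:
            try:
                uni = univariate_eta2(y, meta[col])
            except ValueError as exc:
                notes.append(f"{outcome!r} ~ {col!r}: {exc}")
                continue
            rows.append(
                {
                    "outcome": outcome,
                    "variable": col,
                    "eta2_univariate": uni,
                    "eta2_type2": np.nan if multi is None else multi.loc[col, "eta2"],
                    "n_groups": int(
                        meta[col].astype(str).str.strip().replace(
                            {"": np.nan, "NA": np.nan, "NaN": np.nan}
                        ).dropna().nunique()
                    ),
                }
            )
    table = pd.DataFrame(
        rows, columns=["outcome", "variable", "eta2_univariate", "eta2_type2", "n_groups"]
    )
    return table, notes
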