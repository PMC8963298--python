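import math
import warnings

import numpy as np
import pandas as pd
import pytest

from metaboqc import (
    AbundanceMatrix,
    feature_descriptives,
    feature_missingness,
    normality_w,
    outlier_flags,
    sample_missingness,
    total_sum_abundance,
)

from conftest import random_matrix


# ---------------------------------------------------------------- oracles
def brute_sample_missingness(df: pd.DataFrame, excluded=()):
    out = {}
    keep = [c for c in df.columns if c not in set(excluded)]
    for s in df.index:
        n_missing = sum(1 for c in keep if math.isnan(df.loc[s, c]))
        out[s] = n_missing / len(keep)
    return pd.Series(out)


def brute_feature_missingness(df: pd.DataFrame):
    return pd.Series(
        {c: sum(1 for s in df.index if math.isnan(df.loc[s, c])) / len(df.index)
         for c in df.columns}
    )


def brute_tsa(df: pd.DataFrame, complete_only: bool):
    cols = list(df.columns)
    if complete_only:
        cols = [c for c in cols if not df[c].isna().any()]
    z = {}
    for c in cols:
        vals = df[c].dropna()
        z[c] = (df[c] - vals.mean()) / vals.std(ddof=1)
    zdf = pd.DataFrame(z)
    shift = abs(np.nanmin(zdf.to_numpy()))
    out = {}
    for s in df.index:
        out[s] = sum(
            zdf.loc[s, c] + shift for c in cols if not math.isnan(zdf.loc[s, c])
        )
    return pd.Series(out)


def brute_outlier_flags(df: pd.DataFrame, k: float):
    flags = pd.DataFrame(False, index=df.index, columns=df.columns)
    for c in df.columns:
        vals = df[c].dropna()
        med = vals.median()
        iqr = vals.quantile(0.75) - vals.quantile(0.25)
        for s in df.index:
            v = df.loc[s, c]
            if not math.isnan(v) and abs(v - med) > k * iqr:
                flags.loc[s, c] = True
    return flags


# ---------------------------------------------------------------- missingness
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_missingness_matches_brute_force(seed):
    m = random_matrix(seed)
    excl = {"f0", "f3"}
    pd.testing.assert_series_equal(
        sample_missingness(m), brute_sample_missingness(m.data), check_names=False
    )
    pd.testing.assert_series_equal(
        sample_missingness(m, excl),
        brute_sample_missingness(m.data, excl),
        check_names=False,
    )
    pd.testing.assert_series_equal(
        feature_missingness(m), brute_feature_missingness(m.data), check_names=False
    )


def test_missingness_sum_check():
    m = random_matrix(7)
    total = m.data.isna().sum().sum()
    assert sample_missingness(m).sum() * m.n_features == pytest.approx(total)
    assert feature_missingness(m).sum() * m.n_samples == pytest.approx(total)


def test_exclusion_semantics_single_sample():
    df = pd.DataFrame([[1.0, np.nan, 2.0, 3.0]], index=["s"], columns=list("wxyz"))
    m = AbundanceMatrix(df)
    assert sample_missingness(m).iloc[0] == 0.25
    assert sample_missingness(m, {"x"}).iloc[0] == 0.0


def test_all_features_excluded_is_error():
    m = random_matrix(0, n=4, p=2)
    with pytest.raises(ValueError, match="all features excluded"):
        sample_missingness(m, {"f0", "f1"})


# ---------------------------------------------------------------- TSA
def test_tsa_worked_example():
    m = AbundanceMatrix(
        pd.DataFrame({"f1": [1.0, 2, 3], "f2": [2.0, 4, 6]}, index=list("abc"))
    )
    np.testing.assert_allclose(total_sum_abundance(m).to_numpy(), [0, 2, 4], atol=1e-12)


@pytest.mark.parametrize("complete_only", [False, True])
def test_tsa_matches_brute_force(complete_only):
    m = random_matrix(11)
    got = total_sum_abundance(m, complete_only=complete_only)
    want = brute_tsa(m.data, complete_only)
    np.testing.assert_allclose(got.to_numpy(), want.to_numpy(), atol=1e-12)


def test_tsa_constant_feature_dropped_with_warning():
    df = pd.DataFrame({"f1": [1.0, 2, 3], "f2": [5.0, 5, 5]}, index=list("abc"))
    with pytest.warns(UserWarning, match="zero-variance"):
        tsa = total_sum_abundance(AbundanceMatrix(df))
    np.testing.assert_allclose(tsa.to_numpy(), [0, 1, 2], atol=1e-12)


def test_tsa_complete_only_ignores_incomplete_features():
    base = pd.DataFrame({"f1": [1.0, 2, 3, 4]}, index=list("abcd"))
    with_incomplete = base.assign(f2=[2.0, np.nan, 5, 1])
    a = total_sum_abundance(AbundanceMatrix(base), complete_only=True)
    b = total_sum_abundance(AbundanceMatrix(with_incomplete), complete_only=True)
    np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)


def test_tsa_no_complete_features_warns_missing():
    df = pd.DataFrame({"f1": [np.nan, 2, 3], "f2": [2.0, np.nan, 5]}, index=list("abc"))
    with pytest.warns(UserWarning, match="no complete"):
        tsa = total_sum_abundance(AbundanceMatrix(df), complete_only=True)
    assert tsa.isna().all()


# ---------------------------------------------------------------- outliers
def test_outlier_flag_hand_example():
    vals = [float(v) for v in range(1, 10)] + [100.0]
    m = AbundanceMatrix(pd.DataFrame({"f": vals}, index=[f"s{i}" for i in range(10)]))
    flags, per_sample, per_feature = outlier_flags(m, 5)
    assert flags["f"].sum() == 1 and bool(flags.iloc[9, 0])
    assert per_feature["f"] == 1 and per_sample.iloc[9] == 1


def test_all_equal_feature_never_flagged():
    m = AbundanceMatrix(pd.DataFrame({"f": [3.0] * 8}, index=[f"s{i}" for i in range(8)]))
    flags, _, _ = outlier_flags(m, 5)
    assert not flags.to_numpy().any()


@pytest.mark.parametrize("seed", [0, 5])
def test_outlier_flags_match_brute_force(seed):
    m = random_matrix(seed)
    flags, per_sample, per_feature = outlier_flags(m, 2.0)
    want = brute_outlier_flags(m.data, 2.0)
    assert flags.equals(want)
    assert per_sample.equals(want.sum(axis=1))
    assert per_feature.equals(want.sum(axis=0))


@pytest.mark.parametrize("k1,k2", [(1.0, 2.0), (2.0, 5.0)])
def test_outlier_flags_monotone_in_k(k1, k2):
    m = random_matrix(9)
    f1, _, _ = outlier_flags(m, k1)
    f2, _, _ = outlier_flags(m, k2)
    assert (f2.to_numpy() <= f1.to_numpy()).all()  # flags(k2) subset of flags(k1)


# ---------------------------------------------------------------- descriptives
def test_descriptives_hand_example():
    m = AbundanceMatrix(pd.DataFrame({"f": [2.0, 4, 6]}, index=list("abc")))
    d = feature_descriptives(m).loc["f"]
    assert d["n"] == 3 and d["mean"] == 4 and d["sd"] == 2
    assert d["cv"] == 0.5 and abs(d["skew"]) < 1e-12


def test_descriptives_degenerate_n():
    df = pd.DataFrame({"f": [5.0, np.nan, np.nan]}, index=list("abc"))
    d = feature_descriptives(AbundanceMatrix(df)).loc["f"]
    assert d["n"] == 1 and np.isnan(d["sd"]) and np.isnan(d["cv"]) and np.isnan(d["skew"])


def test_descriptives_match_brute_force():
    m = random_matrix(13)
    d = feature_descriptives(m)
    for c in m.data.columns:
        vals = m.data[c].dropna().to_numpy()
        n = vals.size
        mean = vals.sum() / n
        sd = math.sqrt(((vals - mean) ** 2).sum() / (n - 1))
        m3 = ((vals - mean) ** 3).sum() / n
        g1 = m3 / (((vals - mean) ** 2).sum() / n) ** 1.5
        adj = g1 * math.sqrt(n * (n - 1)) / (n - 2)  # adjusted Fisher-Pearson
        assert d.loc[c, "mean"] == pytest.approx(mean, abs=1e-12)
        assert d.loc[c, "sd"] == pytest.approx(sd, abs=1e-12)
        assert d.loc[c, "skew"] == pytest.approx(adj, abs=1e-10)
        assert d.loc[c, "cv"] == pytest.approx(sd / mean, abs=1e-12)


# ---------------------------------------------------------------- Shapiro W
def test_shapiro_normal_sample_high_w():
    rng = np.random.default_rng(42)
    res = normality_w(rng.standard_normal(500) + 10, seed=0)
    assert res.w_raw > 0.99


def test_shapiro_lognormal_improves_under_log10():
    rng = np.random.default_rng(42)
    res = normality_w(np.exp(rng.standard_normal(500)), seed=0)
    assert res.w_log10 > res.w_raw


def test_shapiro_constant_vector_flagged():
    res = normality_w(np.full(50, 3.0), seed=0)
    assert np.isnan(res.w_raw) and res.reason_raw == "zero variance"


def test_shapiro_large_n_subsample_deterministic():
    rng = np.random.default_rng(0)
    vals = rng.standard_normal(6000) + 5
    a = normality_w(vals, seed=3)
    b = normality_w(vals, seed=3)
    assert a.w_raw == b.w_raw and a.w_log10 == b.w_log10
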