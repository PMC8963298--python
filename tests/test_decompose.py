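import numpy as np
import pandas as pd
import pytest

from metaboqc import (
    AbundanceMatrix,
    FeatureAnnotation,
    PipelineConfig,
    acceleration_factor_n,
    cluster_features,
    eligible_features,
    handle_outlier_values,
    impute_standardize,
    outlier_flags,
    parallel_analysis_n,
    pc_outliers,
    run_pca,
)

from conftest import random_matrix


def _blocks_matrix(seed=0, n=120, per_block=4, n_blocks=3, rho=0.95):
    rng = np.random.default_rng(seed)
    factors = rng.standard_normal((n, n_blocks))
    cols = {}
    for b in range(n_blocks):
        for j in range(per_block):
            noise = rng.standard_normal(n)
            g = np.sqrt(rho) * factors[:, b] + np.sqrt(1 - rho) * noise
            cols[f"b{b}_f{j}"] = np.exp(g)
    return AbundanceMatrix(pd.DataFrame(cols, index=[f"s{i}" for i in range(n)]))


class TestEligibility:
    def _annotated(self, df, xeno=(), derived=()):
        m = AbundanceMatrix(df)
        ann = FeatureAnnotation(
            pd.DataFrame(
                {
                    "is_xenobiotic": [c in xeno for c in df.columns],
                    "is_derived": [c in derived for c in df.columns],
                },
                index=df.columns,
            )
        )
        return m, ann

    def test_high_missingness_and_constant_features_excluded(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "ok": rng.random(20) + 1,
                "toomiss": np.where(rng.random(20) < 0.25, np.nan, 1 + rng.random(20)),
                "const": np.ones(20),
            },
            index=[f"s{i}" for i in range(20)],
        )
        df.loc[df.index[:5], "toomiss"] = np.nan  # force > 20% missingness
        df["ok2"] = rng.random(20) + 1
        m, ann = self._annotated(df)
        keep = eligible_features(m, ann, PipelineConfig())
        assert "toomiss" not in keep and "const" not in keep
        assert {"ok", "ok2"} <= set(keep)

    def test_xenobiotics_always_derived_by_flag(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {c: rng.random(10) + 1 for c in ["a", "b", "xeno", "ratio"]},
            index=[f"s{i}" for i in range(10)],
        )
        m, ann = self._annotated(df, xeno={"xeno"}, derived={"ratio"})
        keep = eligible_features(m, ann, PipelineConfig(exclude_derived=False))
        assert "xeno" not in keep and "ratio" in keep
        keep = eligible_features(m, ann, PipelineConfig(exclude_derived=True))
        assert "ratio" not in keep

    def test_too_few_eligible_is_error(self):
        df = pd.DataFrame({"a": np.ones(5), "b": np.arange(5.0)},
                          index=[f"s{i}" for i in range(5)])
        m, ann = self._annotated(df)
        with pytest.raises(ValueError, match="eligible"):
            eligible_features(m, ann, PipelineConfig())


class TestClustering:
    def test_perfect_anticorrelation_is_distance_zero(self):
        x = np.linspace(1, 10, 30)
        m = AbundanceMatrix(
            pd.DataFrame({"up": x, "down": 11 - x}, index=[f"s{i}" for i in range(30)])
        )
        cl = cluster_features(m, ["up", "down"], cut_height=0.1)
        assert cl.distance.loc["up", "down"] == pytest.approx(0.0, abs=1e-12)
        assert cl.k == 1

    def test_planted_blocks_recovered(self):
        m = _blocks_matrix()
        cl = cluster_features(m, m.feature_ids, cut_height=0.5)
        assert cl.k == 3
        assert len(cl.representatives) == 3
        blocks_of_reps = {r.split("_")[0] for r in cl.representatives}
        assert blocks_of_reps == {"b0", "b1", "b2"}

    def test_cut_above_all_merges_single_cluster(self):
        m = _blocks_matrix()
        assert cluster_features(m, m.feature_ids, cut_height=1.0).k == 1

    def test_distance_matrix_properties(self):
        m = random_matrix(4)
        cl = cluster_features(m, m.feature_ids, 0.5)
        d = cl.distance.to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert (d >= 0).all() and (d <= 1).all()
        assert set(cl.labels.index) == set(m.feature_ids)
        assert cl.k == cl.labels.nunique() == len(cl.representatives)

    def test_sparse_pair_gets_unit_distance(self):
        df = pd.DataFrame(
            {
                "a": [1.0, 2, 3, np.nan, np.nan, np.nan],
                "b": [np.nan, np.nan, np.nan, 1.0, 2, 3],
                "c": [1.0, 2, 3, 4, 5, 6],
            },
            index=[f"s{i}" for i in range(6)],
        )
        with pytest.warns(UserWarning, match="share"):
            cl = cluster_features(AbundanceMatrix(df), ["a", "b", "c"], 0.5)
        assert cl.distance.loc["a", "b"] == 1.0

    def test_representative_is_least_missing(self):
        df = pd.DataFrame(
            {
                "gappy": [1.0, np.nan, 3, 4, 5, 6, 7, 8],
                "full": [1.1, 2, 3.1, 4.1, 5.2, 6.1, 7.1, 8.2],
            },
            index=[f"s{i}" for i in range(8)],
        )
        cl = cluster_features(AbundanceMatrix(df), ["gappy", "full"], 0.5)
        assert cl.k == 1 and cl.representatives == ["full"]


class TestImputeStandardize:
    def test_hand_example(self):
        df = pd.DataFrame({"f": [1.0, np.nan, 3.0], "g": [1.0, 2, 4]}, index=list("abc"))
        z = impute_standardize(AbundanceMatrix(df), ["f", "g"])
        np.testing.assert_allclose(z["f"].to_numpy(), [-1, 0, 1], atol=1e-12)

    def test_complete_feature_unchanged_by_imputation(self):
        m = random_matrix(2, miss=0.0)
        z = impute_standardize(m, m.feature_ids)
        expect = (m.data - m.data.mean()) / m.data.std(ddof=1)
        np.testing.assert_allclose(z.to_numpy(), expect.to_numpy(), atol=1e-12)

    def test_all_missing_feature_dropped(self):
        df = pd.DataFrame({"f": [np.nan] * 4, "g": [1.0, 2, 3, 4], "h": [2.0, 1, 4, 3]},
                          index=list("abcd"))
        with pytest.warns(UserWarning, match="all-missing"):
            z = impute_standardize(AbundanceMatrix(df), ["f", "g", "h"])
        assert list(z.columns) == ["g", "h"]


class TestPca:
    def test_rank_one_matrix(self):
        rng = np.random.default_rng(0)
        u = rng.standard_normal(50)
        df = pd.DataFrame(np.outer(u, [1.0, 2.0, -1.0]),
                          index=[f"s{i}" for i in range(50)], columns=list("abc"))
        z = (df - df.mean()) / df.std(ddof=1)
        res = run_pca(z)
        assert res.variance_explained[0] == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_noise_flat_spectrum(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.standard_normal((200, 10)),
                          index=[f"s{i}" for i in range(200)],
                          columns=[f"f{j}" for j in range(10)])
        z = (df - df.mean()) / df.std(ddof=1)
        res = run_pca(z)
        assert np.all(np.abs(res.variance_explained - 0.1) < 0.05)
        assert np.all(np.diff(res.variance_explained) <= 1e-12)

    def test_scores_centered_and_sign_fixed(self):
        m = random_matrix(6, miss=0.0)
        z = (m.data - m.data.mean()) / m.data.std(ddof=1)
        res = run_pca(z)
        assert np.allclose(res.scores.mean(axis=0), 0, atol=1e-9)
        for name in res.loadings.index:
            row = res.loadings.loc[name]
            assert row.iloc[int(np.argmax(row.abs()))] > 0


class TestComponentRetention:
    def test_acceleration_factor_hand_example(self):
        assert acceleration_factor_n([5, 3, 1, 0.5, 0.4, 0.3]) == 2

    def test_minimum_of_two_floor(self):
        # sharp elbow right after PC1 -> raw estimate 1, floored at 2
        assert acceleration_factor_n([10, 1, 0.9, 0.8, 0.7]) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_acceleration_factor_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        e = np.sort(rng.random(12))[::-1]
        best_i, best_a = None, -np.inf
        for i in range(2, len(e)):  # 1-based interior positions
            a = e[i] - 2 * e[i - 1] + e[i - 2]
            if a > best_a:
                best_i, best_a = i, a
        assert acceleration_factor_n(e) == max(best_i - 1, 2)

    def test_parallel_analysis_null_retains_almost_nothing(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.standard_normal((150, 12)))
        z = (df - df.mean()) / df.std(ddof=1)
        res = run_pca(z)
        n = parallel_analysis_n(res.eigenvalues, 150, 12, seed=1)
        assert n <= 1

    def test_parallel_analysis_recovers_planted_factors(self):
        rng = np.random.default_rng(7)
        f = rng.standard_normal((500, 3))
        load = rng.standard_normal((3, 30))
        df = pd.DataFrame(f @ load + 0.5 * rng.standard_normal((500, 30)))
        z = (df - df.mean()) / df.std(ddof=1)
        res = run_pca(z)
        assert parallel_analysis_n(res.eigenvalues, 500, 30, seed=2) == 3

    def test_parallel_analysis_deterministic(self):
        e = [3.0, 1.5, 1.0, 0.8, 0.6]
        a = parallel_analysis_n(e, 100, 5, seed=9)
        b = parallel_analysis_n(e, 100, 5, seed=9)
        assert a == b


class TestPcOutliers:
    def _scores(self, seed=0, n=300, m=4):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.standard_normal((n, m)),
                            index=[f"s{i}" for i in range(n)],
                            columns=[f"PC{j+1}" for j in range(m)])

    def test_planted_extreme_sample_flagged(self):
        scores = self._scores()
        scores.iloc[0, 0] = scores["PC1"].mean() + 8 * scores["PC1"].std(ddof=1)
        assert "s0" in pc_outliers(scores, 2, 5)

    def test_matches_brute_force_loop(self):
        scores = self._scores(3)
        got = set(pc_outliers(scores, 3, 1.8))
        want = set()
        for s in scores.index:
            for c in scores.columns[:3]:
                col = scores[c]
                if abs(scores.loc[s, c] - col.mean()) > 1.8 * col.std(ddof=1):
                    want.add(s)
        assert got == want

    def test_monotone_and_empty_at_infinity(self):
        scores = self._scores(4)
        loose = set(pc_outliers(scores, 2, 3.5))
        tight = set(pc_outliers(scores, 2, 2.0))
        assert loose <= tight
        assert pc_outliers(scores, 2, np.inf) == []


class TestHandleOutlierValues:
    def _matrix(self):
        vals = [float(v) for v in range(1, 10)] + [100.0]
        return AbundanceMatrix(
            pd.DataFrame({"f": vals}, index=[f"s{i}" for i in range(10)])
        )

    def test_winsorize_maps_to_most_extreme_unflagged(self):
        m = self._matrix()
        flags, _, _ = outlier_flags(m, 5)
        out = handle_outlier_values(m, flags, "winsorize")
        assert out.data.loc["s9", "f"] == 9.0

    def test_leave_is_identity(self):
        m = self._matrix()
        flags, _, _ = outlier_flags(m, 5)
        pd.testing.assert_frame_equal(handle_outlier_values(m, flags, "leave").data, m.data)

    def test_to_na_then_impute_gives_median(self):
        m = self._matrix()
        flags, _, _ = outlier_flags(m, 5)
        na = handle_outlier_values(m, flags, "to_na")
        assert np.isnan(na.data.loc["s9", "f"])
        med_without = na.data["f"].median()
        z = impute_standardize(na, ["f"])  # imputed cell sits at the median -> z = 0...
        filled = na.data["f"].fillna(med_without)
        assert filled.loc["s9"] == med_without
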