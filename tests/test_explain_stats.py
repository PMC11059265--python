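import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats
from sklearn.ensemble import RandomForestClassifier

from imusway import explain_stats as es
from imusway import feature_ranking as fr
from imusway.errors import CapacityError, ConfigurationError, EvaluationError

from oracles import bf_shapley


def _fit_forest(n=80, p=6, seed=0, informative=3):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n, p))
    y = (X[:, :informative].sum(axis=1) > 0).astype(int)
    rf = RandomForestClassifier(n_estimators=30, random_state=seed)
    rf.fit(X, y)
    return rf, X, y


class TestShapleyExact:
    def test_additive_model_closed_form(self):
        rng = np.random.default_rng(1)
        background = rng.normal(0, 1, (50, 2))
        fn = lambda Z: Z[:, 0] + Z[:, 1]
        X = rng.normal(0, 1, (5, 2))
        att = es.shapley_attribution(fn, X, background, method="exact")
        expected = X - background.mean(axis=0)
        np.testing.assert_allclose(att.values, expected, atol=1e-10)

    def test_null_player_zero(self):
        rng = np.random.default_rng(2)
        background = rng.normal(0, 1, (30, 3))
        fn = lambda Z: Z[:, 0] ** 2          # features 1, 2 ignored
        X = rng.normal(0, 1, (4, 3))
        att = es.shapley_attribution(fn, X, background, method="exact")
        np.testing.assert_allclose(att.values[:, 1:], 0.0, atol=1e-12)

    def test_local_accuracy(self):
        rf, X, _ = _fit_forest()
        att = es.shapley_attribution(rf, X[:6], X[:40], method="exact")
        preds = rf.predict_proba(X[:6])[:, -1]
        totals = att.base_value + att.values.sum(axis=1)
        np.testing.assert_allclose(totals, preds, atol=1e-6)

    def test_symmetry_duplicated_features(self):
        rng = np.random.default_rng(3)
        background = rng.normal(0, 1, (40, 2))
        background[:, 1] = background[:, 0]
        fn = lambda Z: Z[:, 0] + Z[:, 1]
        x = np.array([[1.3, 1.3]])
        att = es.shapley_attribution(fn, x, background, method="exact")
        assert att.values[0, 0] == pytest.approx(att.values[0, 1], abs=1e-10)

    def test_matches_brute_force_oracle(self):
        rf, X, _ = _fit_forest(p=5)
        fn = lambda Z: rf.predict_proba(Z)[:, -1]
        background = X[:20]
        att = es.shapley_attribution(rf, X[:3], background, method="exact")
        for i in range(3):
            oracle = bf_shapley(fn, X[i], background)
            np.testing.assert_allclose(att.values[i], oracle, atol=1e-10)

    def test_capacity_error_above_12(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (3, 13))
        with pytest.raises(CapacityError, match="monte_carlo"):
            es.shapley_attribution(lambda Z: Z.sum(axis=1), X, X, method="exact")


class TestShapleyMonteCarlo:
    def test_converges_to_exact(self):
        rf, X, _ = _fit_forest(p=6)
        background = X[:25]
        exact = es.shapley_attribution(rf, X[:5], background, method="exact")
        mc = es.shapley_attribution(
            rf, X[:5], background, method="monte_carlo",
            n_permutations=10_000, seed=0,
        )
        assert np.max(np.abs(mc.values - exact.values)) < 0.01

    def test_seeded_determinism(self):
        rf, X, _ = _fit_forest(p=6)
        a = es.shapley_attribution(rf, X[:3], X[:20], method="monte_carlo",
                                   n_permutations=200, seed=7)
        b = es.shapley_attribution(rf, X[:3], X[:20], method="monte_carlo",
                                   n_permutations=200, seed=7)
        np.testing.assert_array_equal(a.values, b.values)

    def test_null_player_zero(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (4, 3))
        att = es.shapley_attribution(
            lambda Z: Z[:, 0], X, X, method="monte_carlo",
            n_permutations=100, seed=0,
        )
        np.testing.assert_allclose(att.values[:, 1:], 0.0, atol=1e-12)


class TestRankOverlap:
    def _score_table(self, names, scores):
        counts = pd.DataFrame({"anova_f": scores}, index=names)
        return fr.FeatureScoreTable(
            counts=counts, final_score=pd.Series(scores, index=names),
            session="EO", n_folds=10, top_k=3,
        )

    def _attribution(self, names, mean_abs):
        values = np.tile(np.asarray(mean_abs, float), (4, 1))
        return es.AttributionSummary(
            values=values, base_value=0.0, feature_names=list(names)
        )

    def test_identical_rankings(self):
        names = list("abcde")
        att = self._attribution(names, [5, 4, 3, 2, 1])
        tbl = self._score_table(names, [10, 8, 6, 4, 2])
        rep = es.rank_overlap(att, tbl, k=3)
        assert rep["overlap"] == 3
        assert rep["jaccard"] == 1.0

    def test_disjoint_rankings(self):
        names = list("abcd")
        att = self._attribution(names, [9, 8, 0, 0])
        tbl = self._score_table(names, [0, 0, 9, 8])
        rep = es.rank_overlap(att, tbl, k=2)
        assert rep["overlap"] == 0
        assert rep["jaccard"] == 0.0

    def test_k_too_large_rejected(self):
        names = list("ab")
        att = self._attribution(names, [1, 2])
        tbl = self._score_table(names, [1, 2])
        with pytest.raises(ConfigurationError):
            es.rank_overlap(att, tbl, k=5)


class TestGroupAnova:
    def test_mmse_row_from_summaries(self):
        _, p = es.group_anova_summary(30, 27.53, 2.029, 30, 25.87, 3.36)
        assert p == pytest.approx(0.02357, rel=0.03)

    def test_gender_row_from_counts(self):
        cn = np.array([1.0] * 16 + [0.0] * 14)
        mci = np.array([1.0] * 20 + [0.0] * 10)
        _, p = es.group_anova(cn, mci)
        assert p == pytest.approx(0.29985, rel=0.03)

    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0])
        f, p = es.group_anova(x, x)
        assert f == 0.0 and p == 1.0

    def test_zero_variance_unequal_means(self):
        f, p = es.group_anova([1.0, 1.0], [2.0, 2.0])
        assert np.isinf(f) and p == 0.0

    def test_matches_pooled_t_test(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a = rng.normal(0, 1, 15)
            b = rng.normal(0.3, 1.2, 12)
            f, p = es.group_anova(a, b)
            t, p_t = spstats.ttest_ind(a, b)
            assert f == pytest.approx(t**2, rel=1e-10)
            assert p == pytest.approx(p_t, rel=1e-10)

    def test_summary_equals_raw(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.5, 1, 25)
        f_raw, p_raw = es.group_anova(a, b)
        f_sum, p_sum = es.group_anova_summary(
            len(a), a.mean(), a.std(ddof=1), len(b), b.mean(), b.std(ddof=1)
        )
        assert f_sum == pytest.approx(f_raw, rel=1e-12)
        assert p_sum == pytest.approx(p_raw, rel=1e-12)

    def test_tiny_group_rejected(self):
        with pytest.raises(EvaluationError):
            es.group_anova([1.0], [2.0, 3.0])


class TestGroupSummary:
    def test_simple_quartiles(self):
        X = pd.DataFrame({"f": [1.0, 2, 3, 4, 5, 10, 20, 30, 40, 50]})
        y = np.array(["CN"] * 5 + ["MCI"] * 5)
        gs = es.group_summary(X, y)
        assert gs.stats.loc[("f", "CN"), "median"] == 3
        assert gs.stats.loc[("f", "CN"), "q1"] == 2
        assert gs.stats.loc[("f", "CN"), "q3"] == 4
        assert gs.direction["f"] == "MCI>CN"

    def test_quartile_ordering_everywhere(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(0, 1, (60, 5)),
                         columns=[f"f{i}" for i in range(5)])
        y = rng.choice(["CN", "MCI"], 60)
        gs = es.group_summary(X, y)
        assert (gs.stats["q1"] <= gs.stats["median"]).all()
        assert (gs.stats["median"] <= gs.stats["q3"]).all()
        assert (gs.stats["whisker_lo"] <= gs.stats["q1"]).all()
        assert (gs.stats["whisker_hi"] >= gs.stats["q3"]).all()

    def test_constant_feature_no_direction(self):
        X = pd.DataFrame({"f": [2.0] * 8})
        y = np.array(["CN"] * 4 + ["MCI"] * 4)
        gs = es.group_summary(X, y)
        assert gs.direction["f"] == "none"
        assert gs.stats.loc[("f", "CN"), "q1"] == gs.stats.loc[("f", "CN"), "q3"]

    def test_percentile_brute_force(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(0, 1, 31)
        X = pd.DataFrame({"f": vals})
        y = np.array(["CN"] * 16 + ["MCI"] * 15)
        gs = es.group_summary(X, y)
        for grp in ("CN", "MCI"):
            sub = vals[y == grp]
            assert gs.stats.loc[("f", grp), "median"] == pytest.approx(
                np.percentile(sub, 50)
            )
            assert gs.stats.loc[("f", grp), "q1"] == pytest.approx(
                np.percentile(sub, 25)
            )

    def test_empty_group_rejected(self):
        X = pd.DataFrame({"f": [1.0, 2.0]})
        y = np.array(["CN", "CN"])
        with pytest.raises(EvaluationError):
            es.group_summary(X, y)


class TestDemographicsTable:
    def test_table_shape_and_pvalues(self):
        rng = np.random.default_rng(10)
        subjects = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(40)],
            "group": ["CN"] * 20 + ["MCI"] * 20,
            "mmse": np.r_[rng.normal(28, 1.5, 20), rng.normal(25, 2.5, 20)],
            "age": rng.normal(75, 4, 40),
            "sex": rng.choice(["M", "F"], 40),
            "height_cm": rng.normal(160, 7, 40),
            "weight_kg": rng.normal(62, 8, 40),
            "education_yr": rng.normal(10, 4, 40),
        })
        table = es.demographics_table(subjects)
        assert len(table) == 6
        assert table["p_value"].between(0, 1).all()
        mmse_p = table.loc[table["variable"] == "mmse", "p_value"].iloc[0]
        assert mmse_p < 0.01
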