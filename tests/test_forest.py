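"""Survival forest internals: log-rank splitting, Nelson-Aalen leaves, OOB
bookkeeping, permutation importance and minimal depth."""

import numpy as np
import pandas as pd
import pytest

import kinotox as kt
from kinotox.forest import ForestConfig, grow_tree, _best_split_all_thresholds

from conftest import (
    oracle_kaplan_meier,
    oracle_logrank,
    oracle_nelson_aalen,
    random_survival_instances,
)


class TestLogrankStatistic:
    def test_hand_case_six_subjects_matches_oracle_and_library(self):
        times = np.array([1, 2, 3, 4, 5, 6], float)
        events = np.ones(6, int)
        left = np.array([True, True, True, False, False, False])
        stat = kt.logrank_split_statistic(times, events, left)
        assert stat == pytest.approx(oracle_logrank(times, events, left), abs=1e-12)
        from lifelines.statistics import logrank_test

        lt = logrank_test(times[left], times[~left], events[left], events[~left])
        assert stat**2 == pytest.approx(lt.test_statistic, rel=1e-9)

    def test_identical_groups_give_zero(self):
        times = np.array([1, 2, 3, 1, 2, 3], float)
        events = np.array([1, 0, 1, 1, 0, 1])
        left = np.array([True, True, True, False, False, False])
        assert kt.logrank_split_statistic(times, events, left) == 0.0

    def test_separated_groups_strictly_positive(self):
        times = np.array([1, 2, 3, 50, 60, 70], float)
        events = np.array([1, 1, 1, 0, 0, 0])
        left = np.array([True, True, True, False, False, False])
        assert kt.logrank_split_statistic(times, events, left) > 0

    def test_no_events_zero_by_convention(self):
        times = np.array([1.0, 2.0, 3.0])
        # a single event shared by both sides at the last time: zero variance
        events = np.array([0, 0, 0])
        with pytest.raises(ValueError):
            kt.logrank_split_statistic(times, events, np.array([True, True, True]))
        assert (
            kt.logrank_split_statistic(times, events, np.array([True, False, False]))
            == 0.0
        )

    @pytest.mark.parametrize("inst", random_survival_instances(25, seed=42),
                             ids=lambda x: f"n{len(x[0])}")
    def test_matches_bruteforce_on_small_instances(self, inst):
        times, events = inst
        rng = np.random.default_rng(len(times))
        left = rng.integers(0, 2, size=len(times)).astype(bool)
        if not left.any() or left.all():
            left[0] = ~left[0]
        got = kt.logrank_split_statistic(times, events, left)
        assert got == pytest.approx(oracle_logrank(times, events, left), abs=1e-10)

    def test_vectorized_threshold_scan_agrees_with_pointwise(self):
        """The all-thresholds scan must reproduce statistic-by-statistic
        evaluation of every midpoint split."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = rng.integers(5, 12)
            x = rng.integers(0, 4, size=n).astype(float)
            times = rng.integers(1, 6, size=n).astype(float)
            events = rng.integers(0, 2, size=n)
            if events.sum() == 0:
                events[0] = 1
            best, thr = _best_split_all_thresholds(x, times, events)
            # pointwise reference
            ref = 0.0
            for cut in np.unique(x)[:-1]:
                stat = kt.logrank_split_statistic(times, events, x <= cut)
                ref = max(ref, stat)
            assert best == pytest.approx(ref, abs=1e-10)
            if best > 0:
                assert kt.logrank_split_statistic(times, events, x <= thr) == (
                    pytest.approx(best, abs=1e-10)
                )


class TestHazardEstimators:
    def test_nelson_aalen_two_events(self):
        curve = kt.nelson_aalen(np.array([1.0, 2.0]), np.array([1, 1]))
        np.testing.assert_allclose(curve.times, [1.0, 2.0])
        np.testing.assert_allclose(curve.chf, [0.5, 1.5])

    def test_nelson_aalen_no_events_is_zero(self):
        curve = kt.nelson_aalen(np.array([5.0, 7.0]), np.array([0, 0]))
        assert (curve.chf == 0).all()

    def test_nelson_aalen_single_subject(self):
        curve = kt.nelson_aalen(np.array([3.0]), np.array([1]))
        assert curve.at(3.0) == 1.0

    @pytest.mark.parametrize("inst", random_survival_instances(25, seed=99),
                             ids=lambda x: f"n{len(x[0])}")
    def test_estimators_match_bruteforce(self, inst):
        times, events = inst
        curve = kt.nelson_aalen(times, events)
        tk, h = oracle_nelson_aalen(times, events)
        np.testing.assert_allclose(curve.times, tk)
        np.testing.assert_allclose(curve.chf, h, atol=1e-10)
        km_t, km_s = kt.kaplan_meier(times, events)
        otk, os_ = oracle_kaplan_meier(times, events)
        np.testing.assert_allclose(km_t, otk)
        np.testing.assert_allclose(km_s, os_, atol=1e-10)

    def test_kaplan_meier_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(5)
        times = rng.integers(1, 10, 40).astype(float)
        events = rng.integers(0, 2, 40)
        km_t, km_s = kt.kaplan_meier(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        ours = pd.Series(km_s, index=km_t)
        theirs = kmf.survival_function_["KM_estimate"]
        for t, s in ours.items():
            assert s == pytest.approx(theirs.loc[t], abs=1e-10)

    def test_hazard_curve_invariants_enforced(self):
        with pytest.raises(ValueError):
            kt.HazardCurve(np.array([1.0, 1.0]), np.array([0.1, 0.2]))
        with pytest.raises(ValueError):
            kt.HazardCurve(np.array([1.0, 2.0]), np.array([0.3, 0.1]))


def _toy_xy(n=80, seed=0, hr=3.0):
    """One strong feature + three noise features, exponential outcomes."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.uniform(size=(n, 4)), columns=list("abcd"))
    rate = 0.02 * hr ** (2 * (X["a"] - 0.5))
    t = np.ceil(rng.exponential(1 / rate)).astype(float)
    event = (t <= 100).astype(int)
    t = np.minimum(t, 100.0)
    return X, t, event


class TestTreeGrowth:
    def test_min_node_size_ge_n_gives_single_leaf_with_full_sample_chf(self):
        X, t, e = _toy_xy(30, seed=1)
        cfg = ForestConfig(n_trees=1, min_node_size=100)
        grid = np.unique(t[e == 1])
        tree = grow_tree(X.to_numpy(), t, e, cfg, np.random.default_rng(0), grid)
        assert tree.n_nodes == 1
        expected = kt.nelson_aalen(t, e, grid=grid)
        np.testing.assert_allclose(tree.leaf_chf[0], expected.chf, atol=1e-12)

    def test_perfectly_separating_predictor_wins_root(self):
        """With one predictor ordering early vs late events, the root must
        split on it at the best exhaustively-verified threshold."""
        rng = np.random.default_rng(2)
        n = 40
        x = np.concatenate([np.zeros(20), np.ones(20)])
        t = np.concatenate([rng.integers(1, 10, 20), rng.integers(90, 100, 20)]).astype(float)
        e = np.ones(n, int)
        X = np.column_stack([x, rng.uniform(size=n)])
        cfg = ForestConfig(n_trees=1, mtry=2, min_node_size=5)
        tree = grow_tree(X, t, e, cfg, np.random.default_rng(0), np.unique(t))
        assert tree.feature[0] == 0
        assert 0 < tree.threshold[0] < 1

    def test_growth_deterministic_under_fixed_rng(self):
        X, t, e = _toy_xy(60, seed=3)
        cfg = ForestConfig(n_trees=1, min_node_size=10)
        grid = np.unique(t[e == 1])
        t1 = grow_tree(X.to_numpy(), t, e, cfg, np.random.default_rng(11), grid)
        t2 = grow_tree(X.to_numpy(), t, e, cfg, np.random.default_rng(11), grid)
        np.testing.assert_array_equal(t1.feature, t2.feature)
        np.testing.assert_array_equal(t1.threshold, t2.threshold)
        np.testing.assert_allclose(t1.leaf_chf, t2.leaf_chf)


class TestForest:
    def test_refuses_all_censored_outcome(self):
        X, t, _ = _toy_xy(20, seed=4)
        with pytest.raises(ValueError, match="zero events"):
            kt.fit_forest(X, t, np.zeros(20, int), ForestConfig(n_trees=2), seed=0)

    def test_reproducible_under_seed(self):
        X, t, e = _toy_xy(60, seed=5)
        f1 = kt.fit_forest(X, t, e, ForestConfig(n_trees=10), seed=42)
        f2 = kt.fit_forest(X, t, e, ForestConfig(n_trees=10), seed=42)
        for a, b in zip(f1.trees, f2.trees):
            np.testing.assert_array_equal(a.feature, b.feature)
            np.testing.assert_array_equal(a.in_bag_idx, b.in_bag_idx)
            np.testing.assert_allclose(a.leaf_chf, b.leaf_chf)
        np.testing.assert_allclose(f1.predict_chf(X), f2.predict_chf(X))
        np.testing.assert_allclose(
            f1.permutation_vimp_all(), f2.permutation_vimp_all()
        )

    def test_oob_fraction_near_bootstrap_expectation(self):
        X, t, e = _toy_xy(100, seed=6)
        forest = kt.fit_forest(X, t, e, ForestConfig(n_trees=60), seed=1)
        frac = np.mean([tree.oob_idx.size / 100 for tree in forest.trees])
        assert frac == pytest.approx(1 / np.e, abs=0.02)

    def test_oob_disjoint_from_in_bag(self):
        X, t, e = _toy_xy(50, seed=7)
        forest = kt.fit_forest(X, t, e, ForestConfig(n_trees=5), seed=2)
        for tree in forest.trees:
            assert not set(tree.oob_idx) & set(tree.in_bag_idx)
            assert set(tree.oob_idx) | set(tree.in_bag_idx) == set(range(50))

    def test_ensemble_chf_is_mean_of_tree_chfs(self):
        X, t, e = _toy_xy(40, seed=8)
        forest = kt.fit_forest(X, t, e, ForestConfig(n_trees=2), seed=3)
        Xa = X.to_numpy()
        manual = (forest.trees[0].predict_chf(Xa) + forest.trees[1].predict_chf(Xa)) / 2
        np.testing.assert_allclose(forest.predict_chf(X), manual, atol=1e-14)

    def test_survival_prediction_invariants(self):
        X, t, e = _toy_xy(60, seed=9)
        forest = kt.fit_forest(X, t, e, ForestConfig(n_trees=10), seed=4)
        S = forest.predict_survival(X)
        assert (S > 0).all() and (S <= 1).all()
        assert (np.diff(S, axis=1) <= 1e-12).all()

    def test_single_leaf_forest_predicts_training_nelson_aalen(self):
        X, t, e = _toy_xy(30, seed=10)
        forest = kt.fit_forest(X, t, e, ForestConfig(n_trees=1, min_node_size=1000), seed=5)
        tree = forest.trees[0]
        in_bag = tree.in_bag_idx
        expected = kt.nelson_aalen(t[in_bag], e[in_bag], grid=forest.grid)
        row = X.iloc[[0]]
        np.testing.assert_allclose(forest.predict_chf(row)[0], expected.chf, atol=1e-12)

    def test_missing_feature_rejected(self):
        X, t, e = _toy_xy(30, seed=11)
        forest = kt.fit_forest(X, t, e, ForestConfig(n_trees=2), seed=6)
        bad = X.copy()
        bad.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing|non-finite"):
            forest.predict_chf(bad)

    def test_risk_ordering_follows_strong_feature(self):
        X, t, e = _toy_xy(150, seed=12, hr=6.0)
        forest = kt.fit_forest(X, t, e, ForestConfig(n_trees=40), seed=7)
        risk = forest.predict_mortality(X)
        hi = X["a"] > 0.75
        lo = X["a"] < 0.25
        assert risk[hi.to_numpy()].mean() > risk[lo.to_numpy()].mean()

    def test_null_outcome_gives_chance_level_oob_concordance(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(rng.uniform(size=(200, 10)))
        X.columns = [f"x{i}" for i in range(10)]
        t = np.ceil(rng.exponential(50, 200))
        e = (t <= 100).astype(int)
        t = np.minimum(t, 100.0)
        forest = kt.fit_forest(X, t, e, ForestConfig(n_trees=100), seed=8)
        assert forest.oob_concordance() == pytest.approx(0.5, abs=0.05)

    def test_json_round_trip_preserves_predictions(self, tmp_path):
        X, t, e = _toy_xy(40, seed=14)
        forest = kt.fit_forest(X, t, e, ForestConfig(n_trees=5), seed=9)
        path = tmp_path / "forest.json"
        forest.to_json(path)
        loaded = kt.SurvivalForest.from_json(path)
        np.testing.assert_allclose(loaded.predict_chf(X), forest.predict_chf(X))
        assert loaded.predictor_names == forest.predictor_names
        np.testing.assert_allclose(
            loaded.minimal_depth_all(), forest.minimal_depth_all()
        )


class TestVariableImportance:
    def test_unused_predictor_has_exactly_zero_vimp(self):
        X, t, e = _toy_xy(60, seed=15)
        X["never"] = 7.0  # constant: no admissible split can use it
        forest = kt.fit_forest(X, t, e, ForestConfig(n_trees=15, mtry=5), seed=10)
        assert all("never" != forest.predictor_names[f]
                   for tr in forest.trees for f in tr.features_used)
        assert forest.permutation_vimp("never") == 0.0

    def test_noise_predictor_vimp_near_zero_averaged(self):
        X, t, e = _toy_xy(100, seed=16, hr=4.0)
        forest = kt.fit_forest(X, t, e, ForestConfig(n_trees=50), seed=11)
        v = forest.permutation_vimp("c", repeats=20, seed=123)
        assert v == pytest.approx(0.0, abs=0.01)

    def test_causal_predictor_outranks_noise(self):
        X, t, e = _toy_xy(150, seed=17, hr=6.0)
        forest = kt.fit_forest(X, t, e, ForestConfig(n_trees=50), seed=12)
        v = forest.permutation_vimp_all()
        names = np.array(forest.predictor_names)
        assert names[np.argmax(v)] == "a"
        assert v[list(names).index("a")] > np.percentile(
            np.delete(v, list(names).index("a")), 95
        )

    def test_unknown_predictor_rejected(self):
        X, t, e = _toy_xy(30, seed=18)
        forest = kt.fit_forest(X, t, e, ForestConfig(n_trees=2), seed=13)
        with pytest.raises(KeyError):
            forest.permutation_vimp("nope")


class TestMinimalDepth:
    def test_sole_informative_predictor_splits_every_root(self):
        rng = np.random.default_rng(19)
        n = 60
        x = rng.uniform(size=n)
        t = np.ceil(200 * np.exp(-3 * x) * rng.exponential(1.0, n) + 1)
        e = np.ones(n, int)
        X = pd.DataFrame({"only": x})
        forest = kt.fit_forest(X, t, e, ForestConfig(n_trees=10, mtry=1), seed=14)
        assert forest.minimal_depth("only") == 0.0

    def test_never_used_predictor_attains_maximal_convention_value(self):
        X, t, e = _toy_xy(50, seed=20)
        X["never"] = 1.0
        forest = kt.fit_forest(X, t, e, ForestConfig(n_trees=8), seed=15)
        expected = np.mean([tr.max_depth + 1 for tr in forest.trees])
        assert forest.minimal_depth("never") == pytest.approx(expected)
        assert forest.minimal_depth("never") == forest.minimal_depth_all().max()

    def test_causal_predictor_shallower_than_noise(self):
        X, t, e = _toy_xy(150, seed=21, hr=6.0)
        forest = kt.fit_forest(X, t, e, ForestConfig(n_trees=40), seed=16)
        depths = forest.minimal_depth_all()
        names = list(forest.predictor_names)
        assert depths[names.index("a")] < min(
            depths[names.index(k)] for k in "bcd"
        )


class TestLibraryCrossCheck:
    def test_concordance_comparable_to_scikit_survival_forest(self):
        """Independent route: scikit-survival's RSF on the same data should
        reach a similar OOB discrimination level as ours."""
        from sksurv.ensemble import RandomSurvivalForest
        from sksurv.util import Surv

        X, t, e = _toy_xy(150, seed=22, hr=6.0)
        ours = kt.fit_forest(X, t, e, ForestConfig(n_trees=100), seed=17)
        theirs = RandomSurvivalForest(
            n_estimators=100, min_samples_leaf=15, random_state=0, oob_score=True
        ).fit(X.to_numpy(), Surv.from_arrays(e.astype(bool), t))
        assert abs(ours.oob_concordance() - theirs.oob_score_) < 0.1
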