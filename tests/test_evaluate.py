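"""Evaluation primitives against hand computations and independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from scipy import stats as sps

from uaiscore import (
    SimulationConfig,
    benefit_analysis,
    combine_modalities,
    cox_fit,
    km_fit,
    logrank_test,
    simulate_trial,
    time_dependent_auc,
)


class TestKaplanMeier:
    def test_uncensored_equals_empirical_survival(self):
        t = np.array([1.0, 2.0, 3.0])
        km = km_fit(t, [1, 1, 1], ["a"] * 3)["a"]
        # S = 2/3 after t=1, 1/3 after t=2, 0 after t=3
        lookup = dict(zip(km.times, km.survival))
        assert lookup[1.0] == pytest.approx(2 / 3)
        assert lookup[2.0] == pytest.approx(1 / 3)
        assert lookup[3.0] == pytest.approx(0.0)

    def test_all_censored_survival_stays_one(self):
        km = km_fit([1.0, 2.0, 3.0], [0, 0, 0], ["a"] * 3)["a"]
        assert (km.survival == 1.0).all()

    def test_mixed_toy_matches_hand_computed_table(self, toy_surv):
        km = km_fit(toy_surv["time"], toy_surv["event"], ["a"] * 6)["a"]
        lookup = dict(zip(km.times, km.survival))
        assert lookup[1.0] == pytest.approx(5 / 6)
        assert lookup[3.0] == pytest.approx(5 / 6 * 3 / 4)
        assert lookup[4.0] == pytest.approx(5 / 6 * 3 / 4 * 1 / 3)
        assert lookup[5.0] == pytest.approx(lookup[4.0])  # censoring: flat

    def test_survival_monotone_from_one_within_unit_interval(self, toy_surv):
        km = km_fit(toy_surv["time"], toy_surv["event"], ["a"] * 6)["a"]
        assert km.survival[0] <= 1.0
        assert (np.diff(km.survival) <= 1e-12).all()
        assert ((km.survival >= 0) & (km.survival <= 1)).all()

    def test_empty_group_errors_by_name(self):
        labels = pd.Categorical(["a", "a"], categories=["a", "ghost"])
        with pytest.raises(ValueError, match="ghost"):
            km_fit([1.0, 2.0], [1, 1], labels)
        with pytest.raises(ValueError, match="empty"):
            km_fit([], [], [])


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = [1.0, 2, 3, 1, 2, 3]
        e = [1, 1, 0, 1, 1, 0]
        g = ["a"] * 3 + ["b"] * 3
        stat, p = logrank_test(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_single_group_errors(self):
        with pytest.raises(ValueError, match="two groups"):
            logrank_test([1.0, 2.0], [1, 1], ["a", "a"])

    def test_complete_separation_toy_matches_permutation_tail(self):
        # 4 samples, complete separation: the observed statistic is the
        # most extreme of all C(4,2)=6 group assignments (attained twice)
        t = np.array([1.0, 2.0, 8.0, 9.0])
        e = np.ones(4, int)
        obs, _ = logrank_test(t, e, ["lo", "lo", "hi", "hi"])
        stats = []
        for comb in itertools.combinations(range(4), 2):
            g = np.array(["lo"] * 4, dtype=object)
            g[list(comb)] = "hi"
            s, _ = logrank_test(t, e, g)
            stats.append(s)
        assert obs == pytest.approx(max(stats))
        assert np.mean(np.array(stats) >= obs - 1e-12) == pytest.approx(2 / 6)

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(0)
        rejections = 0
        reps = 400
        for _ in range(reps):
            t = rng.exponential(1.0, 60)
            e = (rng.random(60) < 0.8).astype(int)
            g = np.array(["a"] * 30 + ["b"] * 30)
            _, p = logrank_test(t, e, g)
            rejections += p < 0.05
        assert 0.03 < rejections / reps < 0.07

    def test_two_group_statistic_equals_cox_score_test(self):
        # the Mantel-Cox statistic is the Cox partial-likelihood score test
        # for a binary covariate; compute U(0)^2 / I(0) from first principles
        rng = np.random.default_rng(1)
        n = 80
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(np.exp(-0.5 * x))
        e = (rng.random(n) < 0.7).astype(int)
        order = np.argsort(t)
        ts, es, xs = t[order], e[order], x[order]
        U = I = 0.0
        for i in range(n):
            if es[i] != 1:
                continue
            risk = ts >= ts[i]
            m = xs[risk].mean()
            U += xs[i] - m
            I += xs[risk].var()
        g = np.where(x == 1, "hi", "lo")
        stat, _ = logrank_test(t, e, g)
        assert stat == pytest.approx(U**2 / I, rel=1e-10)


class TestCox:
    def test_recovers_true_hazard_ratio_two(self):
        rng = np.random.default_rng(2)
        n = 2000
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(1.0 / np.exp(np.log(2.0) * x))
        res = cox_fit(pd.DataFrame({"x": x}), t, np.ones(n, int))
        hr = res.hr("x")
        assert 1.8 <= hr <= 2.2
        assert res.summary.loc["x", "ci_low"] <= hr <= res.summary.loc["x", "ci_high"]

    def test_null_covariate_p_values_uniform(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(120):
            x = rng.normal(size=80)
            t = rng.exponential(1.0, 80)
            e = (rng.random(80) < 0.8).astype(int)
            ps.append(cox_fit(pd.DataFrame({"x": x}), t, e).summary.loc["x", "p"])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_duplicated_covariate_flagged_as_collinear(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        res = cox_fit(
            pd.DataFrame({"a": x, "b": x}), rng.exponential(1, 50), np.ones(50, int)
        )
        assert res.flagged
        assert "collinear" in res.diagnostics

    def test_constant_covariate_raises(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit(pd.DataFrame({"a": [1.0, 1.0, 1.0]}), [1, 2, 3], [1, 1, 1])

    def test_hr_invariant_to_time_rescaling(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=150)
        t = rng.exponential(np.exp(-0.5 * x))
        e = (rng.random(150) < 0.7).astype(int)
        h1 = cox_fit(pd.DataFrame({"x": x}), t, e).hr("x")
        h2 = cox_fit(pd.DataFrame({"x": x}), 37.0 * t, e).hr("x")
        assert h1 == pytest.approx(h2, rel=1e-8)


def _brute_force_ipcw_auc(scores, times, events, t):
    """Exhaustive weighted pair enumeration (independent of the implementation)."""
    kmf = KaplanMeierFitter().fit(times, 1 - np.asarray(events))

    def G_minus(u):  # left limit of the censoring KM
        return float(kmf.survival_function_at_times(u - 1e-9).iloc[0])

    num = den_case = 0.0
    n_controls = int((times > t).sum())
    for i in range(len(times)):
        if not (times[i] <= t and events[i] == 1):
            continue
        w = 1.0 / G_minus(times[i])
        den_case += w
        for j in range(len(times)):
            if times[j] > t:
                num += w * ((scores[i] > scores[j]) + 0.5 * (scores[i] == scores[j]))
    return num / (den_case * n_controls)


class TestTimeDependentAUC:
    def test_perfect_ranking_gives_auc_one(self):
        t = np.arange(1.0, 9.0)
        e = np.ones(8, int)
        sc = -t  # higher score = earlier event = perfect risk ranking
        curve = time_dependent_auc(sc, t, e, [2.5, 5.5], n_bootstrap=0)
        assert np.allclose(curve.auc, 1.0)

    def test_random_score_near_half_within_ci(self):
        rng = np.random.default_rng(6)
        n = 150
        t = rng.exponential(1.0, n)
        e = (rng.random(n) < 0.75).astype(int)
        sc = rng.normal(size=n)
        curve = time_dependent_auc(sc, t, e, [0.3, 0.7, 1.2], n_bootstrap=100, seed=0)
        assert (curve.ci_low <= 0.5).all() and (curve.ci_high >= 0.5).all()

    def test_censored_toy_matches_brute_force_pair_enumeration(self):
        t = np.array([1.0, 2.0, 2.5, 3.0, 4.0, 5.0, 6.0, 7.0])
        e = np.array([1, 0, 1, 1, 0, 1, 0, 1])
        sc = np.array([5.0, 4.0, 4.0, 3.0, 2.5, 2.0, 1.0, 0.5])
        for horizon in (2.7, 4.5):
            curve = time_dependent_auc(sc, t, e, [horizon], n_bootstrap=0)
            brute = _brute_force_ipcw_auc(sc, t, e, horizon)
            assert curve.auc[0] == pytest.approx(brute, abs=1e-12)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        n = 100
        t = rng.exponential(1.0, n)
        e = (rng.random(n) < 0.7).astype(int)
        sc = rng.normal(size=n)
        a = time_dependent_auc(sc, t, e, [0.5, 1.0], n_bootstrap=0)
        b = time_dependent_auc(np.exp(sc), t, e, [0.5, 1.0], n_bootstrap=0)
        assert np.allclose(a.auc, b.auc)

    def test_matches_scikit_survival_estimator(self):
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        rng = np.random.default_rng(8)
        n = 200
        sc = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.8 * sc))
        e = (rng.random(n) < 0.7).astype(int)
        horizons = np.quantile(t[e == 1], [0.25, 0.5, 0.75])
        y = Surv.from_arrays(e.astype(bool), t)
        ref, _ = cumulative_dynamic_auc(y, y, sc, horizons)
        ours = time_dependent_auc(sc, t, e, horizons, n_bootstrap=0)
        assert np.allclose(ours.auc, ref, atol=1e-10)

    def test_eval_times_beyond_follow_up_dropped_with_warning(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 1, 0])
        with pytest.warns(UserWarning, match="dropping"):
            curve = time_dependent_auc([3.0, 2, 1, 0], t, e, [2.0, 99.0], n_bootstrap=0)
        assert list(curve.times) == [2.0]


class TestCombineModalities:
    def _data(self, seed=9, n=300, beta_ctdna=0.7):
        rng = np.random.default_rng(seed)
        ids = [f"s{i}" for i in range(n)]
        score = pd.Series(rng.normal(size=n), index=ids)
        ctdna = pd.Series((rng.random(n) < 0.4).astype(float), index=ids)
        lp = 0.8 * score + beta_ctdna * ctdna
        t = pd.Series(rng.exponential(np.exp(-lp)), index=ids)
        e = pd.Series((rng.random(n) < 0.8).astype(int), index=ids)
        return score, ctdna, t, e, ids

    def test_single_component_is_monotone_transform(self):
        score, _, t, e, ids = self._data()
        combo = combine_modalities({"score": score}, t, e, ids[:150])
        rho = sps.spearmanr(combo.risk, score).statistic
        assert abs(rho) == pytest.approx(1.0)

    def test_adding_noise_component_never_hurts_training_likelihood(self):
        score, ctdna, t, e, ids = self._data()
        rng = np.random.default_rng(10)
        noise = pd.Series((rng.random(300) < 0.5).astype(float), index=score.index)
        from uaiscore.evaluate import cox_fit as _fit

        base = _fit(pd.DataFrame({"s": score}), t, e)
        ext = _fit(pd.DataFrame({"s": score, "z": noise}), t, e)
        assert ext.log_likelihood >= base.log_likelihood - 1e-8

    def test_missing_components_flagged_not_scored(self):
        score, ctdna, t, e, ids = self._data()
        ctdna.iloc[:20] = np.nan
        combo = combine_modalities({"score": score, "ctdna": ctdna}, t, e, ids[:150])
        assert combo.risk.iloc[:20].isna().all()
        assert not combo.complete.iloc[:20].any()
        assert combo.benefit.equals(-combo.risk)

    def test_logistic_landmark_alternative_agrees_in_rank(self):
        # both combination rules should rank a strong continuous signal
        # plus a binary one consistently
        score, ctdna, t, e, ids = self._data(seed=11, n=400)
        cox = combine_modalities({"s": score, "c": ctdna}, t, e, ids[:250])
        logi = combine_modalities(
            {"s": score, "c": ctdna}, t, e, ids[:250], method="logistic_landmark"
        )
        rho = sps.spearmanr(cox.risk, logi.risk).statistic
        assert rho > 0.9
        with pytest.raises(ValueError, match="unknown combination method"):
            combine_modalities({"s": score}, t, e, ids[:250], method="gbm")

    def test_no_complete_training_cases_errors(self):
        score, ctdna, t, e, ids = self._data()
        ctdna.iloc[:150] = np.nan
        with pytest.raises(ValueError, match="complete"):
            combine_modalities({"score": score, "ctdna": ctdna}, t, e, ids[:150])

    def test_ctdna_signal_improves_held_out_auc_over_score_alone(self):
        # Monte-Carlo oracle on the generating model: when ctDNA carries
        # independent hazard signal, the combination cannot do meaningfully
        # worse than the score alone at the median event time
        deltas = []
        for seed in range(10):
            score, ctdna, t, e, ids = self._data(seed=seed, n=400)
            train, test = ids[:200], ids[200:]
            combo = combine_modalities(
                {"score": score, "ctdna": ctdna}, t, e, train
            )
            horizon = float(np.median(t[e == 1]))
            a_combo = time_dependent_auc(
                combo.risk[test], t[test], e[test], [horizon], n_bootstrap=0
            ).auc[0]
            a_alone = time_dependent_auc(
                score[test], t[test], e[test], [horizon], n_bootstrap=0
            ).auc[0]
            deltas.append(a_combo - a_alone)
        assert np.mean(deltas) >= -0.02


class TestBenefitAnalysis:
    @staticmethod
    def _scores_clinical(seed=0, n=400, effect=True):
        rng = np.random.default_rng(seed)
        ids = [f"s{i}" for i in range(n)]
        group = np.where(rng.random(n) < 0.5, "high", "low")
        arm = np.where(rng.random(n) < 0.5, "IO", "Obs")
        lp = np.zeros(n)
        if effect:
            lp = np.where((group == "high") & (arm == "IO"), -1.0, 0.0)
        t = rng.exponential(np.exp(-lp))
        clin = pd.DataFrame(
            {
                "sample_id": ids,
                "arm": arm,
                "dfs_time": t,
                "dfs_event": (rng.random(n) < 0.8).astype(int),
                "os_time": t + 0.5,
                "os_event": (rng.random(n) < 0.7).astype(int),
            }
        ).set_index("sample_id", drop=False)
        scores = pd.DataFrame(
            {"sample_id": ids, "uaiscore": rng.normal(size=n), "group": group}
        ).set_index("sample_id", drop=False)
        return scores, clin

    def test_treatment_benefit_confined_to_high_stratum(self):
        scores, clin = self._scores_clinical(effect=True)
        res = benefit_analysis(scores, clin)
        high = res["by_stratum"]["high"]
        low = res["by_stratum"]["low"]
        assert high["cox"].hr("io") < 1
        assert high["logrank_p"] < 0.05
        assert low["cox"].summary.loc["io", "ci_high"] >= 1

    def test_no_effect_gives_hr_near_one_both_strata(self):
        scores, clin = self._scores_clinical(seed=1, effect=False)
        res = benefit_analysis(scores, clin)
        for stratum in ("high", "low"):
            s = res["by_stratum"][stratum]["cox"].summary
            assert s.loc["io", "ci_low"] <= 1 <= s.loc["io", "ci_high"]

    def test_permuted_arm_labels_cover_null(self):
        covered = 0
        for rep in range(10):
            scores, clin = self._scores_clinical(seed=100 + rep, effect=False)
            res = benefit_analysis(scores, clin)
            ok = all(
                res["by_stratum"][st]["cox"].summary.loc["io", "ci_low"]
                <= 1
                <= res["by_stratum"][st]["cox"].summary.loc["io", "ci_high"]
                for st in ("high", "low")
            )
            covered += ok
        assert covered >= 8

    def test_stratum_missing_an_arm_skipped_with_warning(self):
        scores, clin = self._scores_clinical(seed=2)
        clin.loc[scores.index[scores["group"] == "high"], "arm"] = "IO"
        with pytest.warns(UserWarning, match="lacks"):
            res = benefit_analysis(scores, clin)
        assert "high" not in res["by_stratum"]
        assert "low" in res["by_stratum"]
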