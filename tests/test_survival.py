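"""Kaplan-Meier, log-rank, Cox PH (vs lifelines as an independent oracle),
maximally selected cutpoints and AUC."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as ll_logrank

from tmescore import (
    SurvivalData,
    TMEScoreError,
    cox_fit,
    km_curve,
    logrank_test,
    optimal_cutpoint,
    roc_auc,
    univariate_screen,
)


def _sim_cox(rng, n=500, beta=np.log(2), censor_frac=0.3):
    x = rng.integers(0, 2, n).astype(float)
    rate = 0.01 * np.exp(beta * x)
    t = rng.exponential(1 / rate)
    if censor_frac > 0:
        c = rng.uniform(0, np.quantile(t, 1 - censor_frac) * 2.2, n)
        times, events = np.minimum(t, c), (t <= c).astype(int)
    else:
        times, events = t, np.ones(n, int)
    return times, events, x


class TestKM:
    def test_hand_product_limit(self):
        km = km_curve(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]))
        np.testing.assert_allclose(km["survival"], [2 / 3, 1 / 3, 0.0])
        assert km["at_risk"].tolist() == [3, 2, 1]

    def test_all_censored_is_flat(self):
        km = km_curve(np.array([1.0, 2.0]), np.array([0, 0]))
        assert km.empty  # no steps: S(t) = 1 throughout

    def test_censoring_reduces_risk_set_without_step(self):
        km = km_curve(np.array([1.0, 2.0, 3.0]), np.array([1, 0, 1]))
        np.testing.assert_allclose(km["survival"], [2 / 3, 0.0])
        assert km["at_risk"].tolist() == [3, 1]

    def test_time_scale_equivariance(self, rng):
        t = rng.exponential(10, 30) + 0.1
        e = rng.integers(0, 2, 30)
        e[0] = 1
        a = km_curve(t, e)
        b = km_curve(2 * t, e)
        np.testing.assert_allclose(b["time"], 2 * a["time"])
        np.testing.assert_allclose(b["survival"], a["survival"])


def _hand_logrank_two_groups(times, events, member):
    """Independent O/E/V tabulation, scalar loops only."""
    O = E = V = 0.0
    for v in sorted(set(times[events == 1])):
        at = times >= v
        n = at.sum()
        n1 = (at & member).sum()
        d = ((times == v) & (events == 1)).sum()
        d1 = ((times == v) & (events == 1) & member).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n - d) / (n - 1) * n1 * (n - n1) / n**2
    return (O - E) ** 2 / V


class TestLogrank:
    def test_identical_groups_give_zero(self):
        t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        e = np.array([1, 1, 0, 1, 1, 0])
        g = np.repeat([0, 1], 3)
        chi2, df, p = logrank_test(t, g, events=e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_oracle_ten_subjects(self):
        times = np.array([3.0, 5, 7, 9, 11, 2, 4, 6, 8, 10])
        events = np.array([1, 1, 0, 1, 1, 1, 1, 1, 0, 1])
        member = np.repeat([False, True], 5)
        chi2, df, p = logrank_test(times, member.astype(int), events=events)
        assert df == 1
        assert chi2 == pytest.approx(_hand_logrank_two_groups(times, events, member), abs=1e-9)

    def test_matches_lifelines(self, rng):
        t, e, x = _sim_cox(rng, n=120)
        chi2, _, p = logrank_test(t, x, events=e)
        ll = ll_logrank(t[x == 0], t[x == 1], e[x == 0], e[x == 1])
        assert chi2 == pytest.approx(ll.test_statistic, rel=1e-6)
        assert p == pytest.approx(ll.p_value, rel=1e-6)

    def test_three_group_df(self, rng):
        t = rng.exponential(10, 90) + 0.1
        e = np.ones(90, int)
        g = np.repeat([0, 1, 2], 30)
        chi2, df, p = logrank_test(t, g, events=e)
        assert df == 2
        assert 0 <= p <= 1

    def test_single_group_errors(self):
        with pytest.raises(TMEScoreError, match=">=2 groups"):
            logrank_test(np.array([1.0, 2.0]), [0, 0], events=np.array([1, 1]))


class TestCoxFit:
    def test_matches_lifelines(self, rng):
        t, e, x = _sim_cox(rng, n=300)
        z = rng.normal(size=300)
        fit = cox_fit(SurvivalData(t, e), np.column_stack([x, z]))
        df = pd.DataFrame({"T": t, "E": e, "x": x, "z": z})
        ll = CoxPHFitter().fit(df, duration_col="T", event_col="E")
        np.testing.assert_allclose(fit.summary["beta"], ll.params_[["x", "z"]], atol=1e-5)
        np.testing.assert_allclose(fit.summary["se"], ll.standard_errors_[["x", "z"]], atol=1e-5)
        assert fit.loglik == pytest.approx(ll.log_likelihood_, rel=1e-6)
        assert fit.converged

    def test_efron_equals_breslow_without_ties(self, rng):
        t = rng.exponential(10, 80) + rng.uniform(0, 1e-3, 80)  # unique times
        e = np.ones(80, int)
        x = rng.normal(size=(80, 1))
        a = cox_fit(SurvivalData(t, e), x, ties="efron")
        b = cox_fit(SurvivalData(t, e), x, ties="breslow")
        np.testing.assert_allclose(a.summary["beta"], b.summary["beta"], atol=1e-10)

    def test_score_test_equals_logrank_without_ties(self, rng):
        t = np.sort(rng.exponential(10, 60)) + np.arange(60) * 1e-4
        e = np.ones(60, int)
        x = rng.integers(0, 2, 60).astype(float)
        fit = cox_fit(SurvivalData(t, e), x[:, None])
        chi2, _, p = logrank_test(t, x, events=e)
        assert fit.score_chi2 == pytest.approx(chi2, abs=1e-6)
        assert fit.score_p == pytest.approx(p, abs=1e-6)

    def test_constant_covariate_errors(self, rng):
        t, e, _ = _sim_cox(rng, n=30)
        with pytest.raises(TMEScoreError, match="constant"):
            cox_fit(SurvivalData(t, e), np.ones((30, 1)))

    def test_separation_is_capped_and_warned(self):
        t = np.concatenate([np.arange(1, 11), np.arange(100, 110)]).astype(float)
        e = np.ones(20, int)
        x = np.repeat([1.0, 0.0], 10)  # x=1 always fails first
        with pytest.warns(UserWarning, match="monotone"):
            fit = cox_fit(SurvivalData(t, e), x[:, None])
        assert abs(fit.summary["beta"].iloc[0]) <= 15.0

    def test_beta_recovered_on_average(self):
        betas = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            t, e, x = _sim_cox(rng, n=500)
            betas.append(cox_fit(SurvivalData(t, e), x[:, None]).summary["beta"].iloc[0])
        assert np.mean(betas) == pytest.approx(np.log(2), abs=0.1)


class TestUnivariateScreen:
    def test_planted_gene_flagged_noise_mostly_not(self):
        rng = np.random.default_rng(3)
        n = 200
        g = rng.normal(size=n)
        rate = 0.01 * np.exp(np.log(2) * g)
        t = rng.exponential(1 / rate)
        e = np.ones(n, int)
        noise = rng.normal(size=(30, n))
        features = pd.DataFrame(np.vstack([g, noise]), index=["planted"] + [f"n{i}" for i in range(30)])
        tab = univariate_screen(features, SurvivalData(t, e))
        assert tab.loc["planted", "representative"]
        assert tab.loc["planted", "hr"] > 1
        assert tab.loc[[f"n{i}" for i in range(30)], "representative"].mean() <= 0.2

    def test_constant_feature_skipped(self, rng):
        t, e, _ = _sim_cox(rng, n=40)
        features = pd.DataFrame({"const": np.ones(40), "ok": rng.normal(size=40)}).T
        tab = univariate_screen(features, SurvivalData(t, e))
        assert tab.loc["const", "skipped"]
        assert not tab.loc["ok", "skipped"]


class TestCutpoint:
    def _changepoint_data(self, rng, n=300, pctl=0.6, hr=3.0):
        score = rng.normal(size=n)
        cut = np.quantile(score, pctl)
        rate = 0.01 * np.exp(np.log(hr) * (score > cut))
        t = rng.exponential(1 / rate)
        return score, t, np.ones(n, int), cut

    def test_recovers_planted_changepoint(self):
        errs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            score, t, e, true_cut = self._changepoint_data(rng)
            res = optimal_cutpoint(score, SurvivalData(t, e))
            errs.append(abs((score <= res.cutoff).mean() - 0.6) * 100)
        assert np.median(errs) <= 10

    def test_minprop_respected(self, rng):
        score, t, e, _ = self._changepoint_data(rng, n=100)
        res = optimal_cutpoint(score, SurvivalData(t, e), minprop=0.25)
        frac_hi = (score > res.cutoff).mean()
        assert 0.25 <= frac_hi <= 0.75

    def test_beats_median_split(self, rng):
        score, t, e, _ = self._changepoint_data(rng)
        res = optimal_cutpoint(score, SurvivalData(t, e))
        med_member = score > np.median(score)
        chi2_med, _, _ = logrank_test(t, med_member.astype(int), events=e)
        assert res.chi2 >= chi2_med - 1e-9

    def test_null_permutation_p_not_extreme(self, rng):
        score = rng.normal(size=120)
        t = rng.exponential(100, 120)
        res = optimal_cutpoint(score, SurvivalData(t, np.ones(120, int)), n_permutations=100, seed=0)
        assert res.p_permutation > 0.05
        assert res.p_permutation >= res.p  # multiplicity correction can only grow p

    def test_constant_score_errors(self, rng):
        t, e, _ = _sim_cox(rng, n=30)
        with pytest.raises(TMEScoreError, match="constant"):
            optimal_cutpoint(np.ones(30), SurvivalData(t, e))


class TestAUC:
    def test_hand_examples(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert roc_auc([1, 3, 2, 4], [0, 0, 1, 1]) == 0.75

    def test_independent_score_near_half(self, rng):
        y = rng.integers(0, 2, 2000)
        s = rng.normal(size=2000)
        assert roc_auc(s, y) == pytest.approx(0.5, abs=0.03)

    def test_single_class_errors(self):
        with pytest.raises(TMEScoreError):
            roc_auc([1.0, 2.0], [1, 1])
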