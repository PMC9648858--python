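"""Kaplan-Meier, log-rank cutpoints, Cox regression, C-index, calibration."""

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from diffnet.survival import (
    CoxFit,
    SurvivalData,
    c_index,
    cox_fit,
    hosmer_lemeshow,
    km_logrank,
    nomogram_table,
    optimal_cutpoint,
    risk_score,
)


def _exp_surv(n, rng, hazard=0.02, censor=100.0):
    t = rng.exponential(1 / hazard, n)
    c = np.full(n, censor)
    return np.minimum(t, c), (t <= c).astype(int)


def _cox_sim(n, rng, log_hr=0.7, shape=1.2, scale=80.0, censor=(60, 120)):
    x = rng.standard_normal(n)
    lp = log_hr * x
    t = scale * (-np.log(rng.uniform(size=n)) / np.exp(lp)) ** (1 / shape)
    c = rng.uniform(*censor, size=n)
    time = np.maximum(np.minimum(t, c), 1e-9)
    event = (t <= c).astype(int)
    return x, SurvivalData(time, event, pd.DataFrame({"x": x}))


class TestSurvivalData:
    def test_rejects_nonpositive_times(self):
        with pytest.raises(ValueError):
            SurvivalData(np.array([1.0, 0.0]), np.array([1, 0]))

    def test_rejects_all_censored(self):
        with pytest.raises(ValueError, match="no events"):
            SurvivalData(np.array([1.0, 2.0]), np.array([0, 0]))


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(50, 200)
        surv = SurvivalData(t, np.ones(200, int))
        km = KaplanMeierFitter().fit(t, np.ones(200))
        for q in np.quantile(t, [0.2, 0.5, 0.8]):
            emp = (t > q).mean()
            assert km.predict(q) == pytest.approx(emp, abs=1e-9)

    def test_identical_groups_give_null_logrank(self, rng):
        t, e = _exp_surv(50, rng)
        surv = SurvivalData(np.r_[t, t], np.r_[e, e])
        res = km_logrank(np.r_[np.zeros(50, int), np.ones(50, int)], surv)
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_curves_start_at_one(self, rng):
        t, e = _exp_surv(60, rng)
        res = km_logrank(np.arange(60) % 2, SurvivalData(t, e))
        for g in (0, 1):
            assert res["curves"][g].iloc[0, 0] == pytest.approx(1.0)

    def test_hazard_ratio_three_is_detected(self):
        """HR=3 between exponential groups, n=100/group: p < 0.001 in >= 95/100."""
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            t0 = r.exponential(75, 100)
            t1 = r.exponential(25, 100)
            t = np.r_[t0, t1]
            c = np.full(200, 150.0)
            surv = SurvivalData(np.minimum(t, c), (t <= c).astype(int))
            res = km_logrank(np.repeat([0, 1], 100), surv)
            hits += res["p"] < 0.001
        assert hits >= 95


class TestOptimalCutpoint:
    def test_matches_bruteforce_logrank_scan(self, rng):
        """The scan equals an exhaustive lifelines log-rank maximization."""
        n = 120
        x = rng.standard_normal(n)
        t, e = _exp_surv(n, rng, hazard=0.02)
        t *= np.exp(-0.5 * x)
        surv = SurvivalData(t, e)
        res = optimal_cutpoint(x, surv, minprop=0.1)

        best_stat, best_cut = -1.0, None
        lo = int(np.ceil(0.1 * n))
        for cut in np.sort(np.unique(x))[:-1]:
            g = x > cut
            if g.sum() < lo or (~g).sum() < lo:
                continue
            if e[g].sum() == 0 or e[~g].sum() == 0:
                continue
            stat = logrank_test(t[g], t[~g], e[g], e[~g]).test_statistic
            if stat > best_stat:
                best_stat, best_cut = stat, cut
        assert res["cut"] == pytest.approx(best_cut)
        assert res["statistic"] ** 2 == pytest.approx(best_stat, rel=1e-6)

    def test_strong_effect_significant(self, rng):
        n = 50
        x = np.arange(n, dtype=float)
        # higher feature value -> earlier progression, deterministic ordering
        t = (n - x) + 1.0
        surv = SurvivalData(t, np.ones(n, int))
        res = optimal_cutpoint(x, surv)
        assert res["p"] < 0.01

    def test_cut_respects_minprop_quantiles(self, rng):
        x = rng.standard_normal(200)
        t, e = _exp_surv(200, rng)
        res = optimal_cutpoint(x, SurvivalData(t, e), minprop=0.1)
        q10, q90 = np.quantile(x, [0.1, 0.9])
        assert q10 - 1e-9 <= res["cut"] <= q90 + 1e-9

    def test_no_admissible_cut_rejected(self):
        surv = SurvivalData(np.arange(1.0, 11.0), np.r_[np.ones(10, int)])
        with pytest.raises(ValueError, match="admissible"):
            optimal_cutpoint(np.ones(10), surv)  # constant feature


class TestCox:
    def test_recovers_log_hazard_ratio(self):
        """True log-HR 0.7: the estimate is close at n=500 (single seed)."""
        _, surv = _cox_sim(500, np.random.default_rng(4))
        fit = cox_fit(surv, ["x"], mode="multivariate", standardize=False)
        assert fit.summary.loc["x", "coef"] == pytest.approx(0.7, abs=0.15)
        assert fit.summary.loc["x", "ci_lower"] <= fit.summary.loc["x", "hr"] <= fit.summary.loc["x", "ci_upper"]

    def test_null_covariate_type_one_error(self):
        """Independent covariate: rejection rate at 0.05 stays near 0.05."""
        rejects = 0
        n_rep = 200
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            x, surv = _cox_sim(80, r, log_hr=0.0)
            fit = cox_fit(surv, ["x"], mode="multivariate")
            rejects += fit.summary.loc["x", "p"] < 0.05
        assert 0.02 <= rejects / n_rep <= 0.09

    def test_constant_covariate_flagged_degenerate(self, rng):
        t, e = _exp_surv(60, rng)
        cov = pd.DataFrame({"c": np.ones(60), "x": rng.standard_normal(60)})
        fit = cox_fit(SurvivalData(t, e, cov), mode="multivariate")
        assert fit.degenerate == ["c"]
        assert fit.summary.loc["c", "coef"] == 0.0
        assert fit.summary.loc["c", "hr"] == 1.0

    def test_univariate_screen_carries_significant_only(self):
        rng = np.random.default_rng(7)
        x, surv = _cox_sim(300, rng, log_hr=0.8)
        noise = rng.standard_normal(300)
        surv = SurvivalData(surv.time, surv.event,
                            pd.DataFrame({"x": x, "noise": noise}))
        uni = cox_fit(surv, mode="univariate-each")
        assert len(uni) == 2
        multi = cox_fit(surv, mode="multivariate", screen_alpha=0.05)
        assert multi.covariates == ["x"]


class TestCIndex:
    def test_perfect_risk_score(self, rng):
        t = rng.exponential(50, 100)
        surv = SurvivalData(t, np.ones(100, int))
        assert c_index(-t, surv) == pytest.approx(1.0)

    def test_random_score_near_half(self, rng):
        t, e = _exp_surv(500, rng)
        surv = SurvivalData(t, e)
        assert c_index(rng.standard_normal(500), surv) == pytest.approx(0.5, abs=0.05)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_pair_enumeration(self, seed):
        """Harrell's C equals explicit usable-pair counting (n <= 100)."""
        r = np.random.default_rng(seed)
        n = 100
        t, e = _exp_surv(n, r, censor=float(r.uniform(30, 80)))
        s = r.standard_normal(n)
        surv = SurvivalData(t, e)
        conc, ties, usable = 0.0, 0.0, 0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                # pair usable if the earlier time is an event
                if t[i] < t[j] and e[i]:
                    usable += 1
                    conc += (s[i] > s[j]) + 0.5 * (s[i] == s[j])
        assert c_index(s, surv) == pytest.approx(conc / usable)


class TestHosmerLemeshow:
    def test_calibrated_probabilities_pass(self):
        """y ~ Bernoulli(p): p-value exceeds 0.05 in >= 90% of replicates."""
        hits = 0
        n_rep = 50
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            p = r.uniform(0.05, 0.95, 2000)
            y = (r.uniform(size=2000) < p).astype(int)
            hits += hosmer_lemeshow(p, y)["p"] > 0.05
        assert hits >= 0.9 * n_rep

    def test_doubled_risk_fails(self):
        r = np.random.default_rng(3)
        p = r.uniform(0.05, 0.45, 2000)
        y = (r.uniform(size=2000) < p).astype(int)
        assert hosmer_lemeshow(np.clip(2 * p, 0, 1), y)["p"] < 0.01

    def test_few_distinct_predictions_collapse(self):
        p = np.repeat([0.2, 0.5, 0.8], 50)
        y = (np.random.default_rng(0).uniform(size=150) < p).astype(int)
        with pytest.warns(UserWarning, match="collapsed"):
            res = hosmer_lemeshow(p, y)
        assert res["bins"] == 3


class TestRiskScoreAndNomogram:
    @pytest.fixture
    def fitted(self):
        rng = np.random.default_rng(11)
        x, surv = _cox_sim(300, rng, log_hr=0.9)
        fit = cox_fit(surv, ["x"], mode="multivariate")
        df = pd.DataFrame({"x": x})
        df["time_months"] = surv.time
        df["event"] = surv.event
        return fit, df, surv

    def test_score_ranking_follows_positive_covariate(self, fitted):
        fit, df, _ = fitted
        rs = risk_score(fit, df)
        assert np.array_equal(np.argsort(rs["scores"]), np.argsort(df["x"].to_numpy()))

    def test_high_risk_group_has_more_events(self, fitted):
        fit, df, _ = fitted
        rs = risk_score(fit, df)
        ev = df["event"].to_numpy()
        assert ev[rs["risk_group"] == 1].sum() > ev[rs["risk_group"] == 0].sum()

    def test_zero_coefficients_give_equal_scores(self, fitted):
        fit, df, _ = fitted
        fit.summary.loc["x", "coef"] = 0.0
        rs = risk_score(fit, df)
        assert np.ptp(rs["scores"]) == 0.0

    def test_nomogram_reference_value_scores_zero(self, fitted):
        fit, df, _ = fitted
        nomo = nomogram_table(fit, horizons=(12, 36, 60))
        pts = nomo["per_covariate"]["x"]["points"].to_numpy()
        assert pts.min() == pytest.approx(0.0)
        assert pts.max() == pytest.approx(100.0)
        # single covariate: points linear in the covariate value
        vals = nomo["per_covariate"]["x"]["value"].to_numpy()
        slope = np.diff(pts) / np.diff(vals)
        assert np.allclose(slope, slope[0])

    def test_nomogram_survival_monotone_in_horizon(self, fitted):
        fit, _, _ = fitted
        nomo = nomogram_table(fit, horizons=(12, 36, 60))
        t2s = nomo["total_to_survival"]
        assert np.all(t2s["surv_12m"] >= t2s["surv_36m"])
        assert np.all(t2s["surv_36m"] >= t2s["surv_60m"])
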