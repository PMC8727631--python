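"""Kaplan-Meier, log-rank, maxstat cutpoints and Cox regression."""

import numpy as np
import pytest

from sescope.simulate import SimulationConfig, simulate_survival
from sescope.survival import (
    cox_fit,
    cut_statistic,
    km_estimate,
    logrank_scores,
    logrank_test,
    maxstat_cutpoint,
    records_to_arrays,
)


class TestKaplanMeier:
    def test_no_events_flat_one(self):
        km = km_estimate(np.array([1.0, 2, 3]), np.array([0, 0, 0]))
        assert km(10.0) == 1.0 and km(0.0) == 1.0

    def test_all_events_equals_empirical_survival(self):
        t = np.array([1.0, 2, 3, 4])
        km = km_estimate(t, np.ones(4, int))
        for x, expected in [(0.5, 1.0), (1.0, 0.75), (2.5, 0.5), (4.0, 0.0)]:
            assert km(x) == pytest.approx(expected)

    def test_eight_record_hand_product(self):
        """Mixed censoring toy, hand-computed product-limit values.

        times  1+ 2  2  3+ 4  5+ 6  7  (+'s censored)
        events at 2: d=2, n=7 -> 5/7; at 4: d=1, n=4 -> 3/4;
        at 6: d=1, n=2 -> 1/2; at 7: d=1, n=1 -> 0.
        """
        t = np.array([1, 2, 2, 3, 4, 5, 6, 7], float)
        e = np.array([0, 1, 1, 0, 1, 0, 1, 1])
        km = km_estimate(t, e)
        assert km(2) == pytest.approx(5 / 7)
        assert km(4) == pytest.approx(5 / 7 * 3 / 4)
        assert km(6) == pytest.approx(5 / 7 * 3 / 4 * 1 / 2)
        assert km(7) == pytest.approx(0.0)

    def test_invariant_nonincreasing_and_tie_order(self, rng):
        t = rng.integers(1, 20, 40).astype(float)
        e = rng.integers(0, 2, 40)
        km = km_estimate(t, e)
        vals = km(np.linspace(0, 25, 200))
        assert np.all(np.diff(vals) <= 1e-15)
        # shuffling within-tie input order changes nothing
        perm = rng.permutation(40)
        km2 = km_estimate(t[perm], e[perm])
        np.testing.assert_allclose(km(np.arange(25.0)), km2(np.arange(25.0)))

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.exponential(10, 100)
        e = rng.integers(0, 2, 100)
        km = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        grid = np.quantile(t, [0.1, 0.3, 0.5, 0.7, 0.9])
        ref = kmf.survival_function_at_times(grid).to_numpy()
        np.testing.assert_allclose(km(grid), ref, atol=1e-10)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate(np.array([-1.0, 2.0]), np.array([1, 1]))


class TestLogrank:
    def test_duplicate_group_null(self):
        t = np.array([1.0, 3, 5, 7])
        e = np.array([1, 0, 1, 1])
        chi2, p = logrank_test((t, e), (t, e))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_subject_hand_accounting(self):
        """O, E, V match per-event-time 2x2 hypergeometric bookkeeping.

        a: (1,death) (3,death) (5,cens); b: (2,death) (4,death) (6,death)
        t=1: n=6,nb=3,d=1 -> E_b += 1/2, V += (3*3*1*5)/(36*5)
        t=2: n=5,nb=3     -> E_b += 3/5, V += (2*3*1*4)/(25*4)
        t=3: n=4,nb=2     -> E_b += 1/2, V += (2*2*1*3)/(16*3)
        t=4: n=3,nb=2     -> E_b += 2/3, V += (1*2*1*2)/(9*2)
        t=6: n=1,nb=1     -> E_b += 1,   V += 0
        O_b = 3 (deaths in b at t = 2, 4, 6)
        """
        ta, ea = np.array([1.0, 3, 5]), np.array([1, 1, 0])
        tb, eb = np.array([2.0, 4, 6]), np.array([1, 1, 1])
        E = 0.5 + 0.6 + 0.5 + 2 / 3 + 1.0
        V = 9 / 36 + 6 / 25 + 4 / 16 + 2 / 9 + 0.0
        chi2, _ = logrank_test((ta, ea), (tb, eb))
        assert chi2 == pytest.approx((3 - E) ** 2 / V, rel=1e-12)

    def test_one_sided_direction(self):
        rng = np.random.default_rng(5)
        t_lo = rng.exponential(20, 100)
        t_hi = rng.exponential(5, 100)
        e = np.ones(100, int)
        z, p = logrank_test((t_lo, e), (t_hi, e), alternative="high_risk_b")
        assert z > 0 and p < 1e-6
        # swapping groups flips the sign of the one-sided deviate
        z2, _ = logrank_test((t_hi, e), (t_lo, e), alternative="high_risk_b")
        assert z2 == pytest.approx(-z, rel=1e-10)

    def test_equals_cox_score_test_no_ties(self):
        """The two-sided log-rank chi-square equals the Cox score statistic
        for the binary group indicator (a classical identity)."""
        rng = np.random.default_rng(8)
        n = 80
        t = rng.exponential(10, n) + rng.random(n) * 1e-6  # no ties
        e = rng.integers(0, 2, n)
        e[:5] = 1
        g = rng.integers(0, 2, n)
        chi2, _ = logrank_test((t[g == 0], e[g == 0]), (t[g == 1], e[g == 1]))
        fit = cox_fit(t, e, g.reshape(-1, 1), ["group"])
        assert fit.score_statistic == pytest.approx(chi2, abs=1e-8)

    def test_no_events_unavailable(self):
        with pytest.raises(ValueError):
            logrank_test((np.array([1.0]), np.array([0])), (np.array([2.0]), np.array([0])))

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        ta, tb = rng.exponential(10, 60), rng.exponential(6, 70)
        ea, eb = rng.integers(0, 2, 60), rng.integers(0, 2, 70)
        ea[0] = eb[0] = 1
        chi2, p = logrank_test((ta, ea), (tb, eb))
        ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-8)
        assert p == pytest.approx(ref.p_value, rel=1e-8)


class TestMaxstat:
    def test_bimodal_marker_recovers_planted_threshold(self):
        """Marker clusters at 1 and 10, hazard doubled above 5: the chosen
        cutpoint falls strictly between the clusters."""
        rng = np.random.default_rng(31)
        n = 200
        marker = np.concatenate([rng.normal(1, 0.2, n // 2), rng.normal(10, 0.2, n // 2)])
        hazard = np.where(marker > 5, 0.2, 0.1)
        t = rng.exponential(1 / hazard)
        e = np.ones(n, int)
        res = maxstat_cutpoint(t, e, marker, n_perm=500, seed=2)
        assert 1.0 < res.cutpoint < 10.0
        # the induced split essentially separates the two clusters
        m_low = int(np.sum(marker <= res.cutpoint))
        assert 85 <= m_low <= 115
        assert res.p_value < 0.05

    def test_maximum_equals_bruteforce_over_candidates(self):
        rng = np.random.default_rng(17)
        n = 60
        t = rng.exponential(10, n)
        e = rng.integers(0, 2, n)
        e[:10] = 1
        marker = rng.normal(0, 1, n)
        res = maxstat_cutpoint(t, e, marker, n_perm=100, seed=0)
        stats_direct = [cut_statistic(t, e, marker, c) for c, _ in res.candidates]
        np.testing.assert_allclose([s for _, s in res.candidates], stats_direct, atol=1e-10)
        assert res.max_statistic == pytest.approx(max(stats_direct), abs=1e-10)
        assert res.cutpoint in [c for c, s in res.candidates if s == max(s for _, s in res.candidates)]

    def test_max_dominates_fixed_cutpoint(self):
        rng = np.random.default_rng(23)
        n = 80
        t, e, marker = rng.exponential(8, n), rng.integers(0, 2, n), rng.normal(5, 1, n)
        e[:10] = 1
        res = maxstat_cutpoint(t, e, marker, n_perm=100, seed=1)
        for c, _ in res.candidates[::3]:
            assert res.max_statistic >= cut_statistic(t, e, marker, c) - 1e-12

    def test_band_too_narrow(self):
        t = np.linspace(1, 20, 20)
        e = np.ones(20, int)
        marker = np.ones(20)
        marker[-1] = 2.0
        with pytest.raises(ValueError):
            maxstat_cutpoint(t, e, marker, epsilon=(0.45, 0.55), n_perm=10, seed=0)

    def test_scores_sum_to_zero_property(self, rng):
        t = rng.exponential(5, 50)
        e = rng.integers(0, 2, 50)
        a = logrank_scores(t, e)
        # log-rank scores are centred residuals: they sum to ~0 (exact when
        # the largest time is an event; bounded by the last increment anyway)
        assert abs(a.sum()) <= 1.0


class TestCox:
    def test_constant_covariate_rejected(self):
        t = np.arange(1.0, 11)
        e = np.ones(10, int)
        with pytest.raises(ValueError):
            cox_fit(t, e, np.ones((10, 1)), ["c"])

    def test_recovers_true_log_hazard_ratio(self):
        """n = 2000 from an exponential model with log-HR 0.7: the estimate
        lands within 0.1 and the 95% CI covers the truth."""
        rng = np.random.default_rng(99)
        n = 2000
        x = rng.integers(0, 2, n)
        t = rng.exponential(1 / (0.05 * np.exp(0.7 * x)))
        c = rng.exponential(40, n)
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
        fit = cox_fit(time, event, x.reshape(-1, 1).astype(float), ["x"])
        beta = fit.coefficients["x"]
        assert fit.converged
        assert abs(beta - 0.7) <= 0.1
        lo, hi = fit.ci95["x"]
        assert lo <= np.exp(0.7) <= hi

    def test_matches_lifelines(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(7)
        n = 300
        X = np.column_stack([rng.integers(0, 2, n), rng.normal(0, 1, n)]).astype(float)
        t = rng.exponential(1 / (0.05 * np.exp(0.5 * X[:, 0] - 0.3 * X[:, 1])))
        e = np.ones(n, int)
        fit = cox_fit(t, e, X, ["a", "b"])
        df = pd.DataFrame({"t": t, "e": e, "a": X[:, 0], "b": X[:, 1]})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        # continuous times: no ties, so Breslow and Efron coincide
        np.testing.assert_allclose(
            [fit.coefficients["a"], fit.coefficients["b"]],
            cph.params_[["a", "b"]].to_numpy(),
            atol=1e-5,
        )

    def test_partial_likelihood_nondecreasing(self):
        recs = simulate_survival(SimulationConfig(seed=41, n_patients=200))
        time, event, marker, X = records_to_arrays(recs, ["age", "grade"])
        high = (marker > 5.35).astype(float)
        fit = cox_fit(time, event, np.column_stack([high, X]), ["high", "age", "grade"])
        assert fit.converged


class TestSimulatedSurvival:
    def test_event_proportion_matches_censor_rate(self):
        cfg = SimulationConfig(seed=77, n_patients=2000, censor_rate=0.3)
        recs = simulate_survival(cfg)
        events = np.array([r.event for r in recs])
        p_hat = events.mean()
        se = np.sqrt(0.7 * 0.3 / 2000)
        assert abs(p_hat - 0.7) <= 3 * se

    def test_zero_censoring_all_events(self):
        recs = simulate_survival(SimulationConfig(seed=1, censor_rate=0.0, n_patients=50))
        assert all(r.event == 1 for r in recs)

    def test_invalid_censor_rate(self):
        with pytest.raises(ValueError):
            SimulationConfig(censor_rate=1.0)
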