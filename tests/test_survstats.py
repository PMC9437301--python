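import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cuproscore.survstats import (
    chi_square_2xk,
    cox_fit_univariate,
    cox_log_partial_likelihood,
    km_curve,
    logrank_test,
    logrank_z,
    optimal_cutpoint,
)


def partial_likelihood_oracle(beta, time, event, x):
    """Explicit Efron partial log-likelihood, written as nested loops over
    event times (independent of the vectorized implementation)."""
    ll = 0.0
    for t in sorted(set(np.asarray(time)[np.asarray(event) == 1])):
        deaths = [i for i in range(len(time)) if time[i] == t and event[i] == 1]
        risk = [i for i in range(len(time)) if time[i] >= t]
        d = len(deaths)
        s_r = sum(np.exp(beta * x[i]) for i in risk)
        s_d = sum(np.exp(beta * x[i]) for i in deaths)
        ll += sum(beta * x[i] for i in deaths)
        for j in range(d):
            ll -= np.log(s_r - (j / d) * s_d)
    return ll


class TestCox:
    def test_mirrored_groups_beta_zero(self):
        time = np.array([5.0, 8, 12, 20, 30, 5, 8, 12, 20, 30])
        event = np.array([1, 1, 0, 1, 0, 1, 1, 0, 1, 0])
        cov = np.repeat([0.0, 1.0], 5)
        res = cox_fit_univariate(time, event, cov)
        assert abs(res.beta) < 1e-8
        assert res.hr == pytest.approx(1.0)

    def test_matches_grid_search_oracle_untied(self):
        rng = np.random.default_rng(0)
        time = np.array([3.0, 5, 7, 11, 13, 17, 19, 23, 29, 31])
        event = np.ones(10, dtype=int)
        event[[2, 7]] = 0
        x = rng.normal(size=10)
        res = cox_fit_univariate(time, event, x)
        grid = np.arange(-3, 3, 1e-4)
        lls = [partial_likelihood_oracle(b, time, event, x) for b in grid]
        beta_grid = grid[int(np.argmax(lls))]
        assert abs(res.beta - beta_grid) < 1e-4

    def test_likelihood_evaluator_matches_oracle_with_ties(self):
        rng = np.random.default_rng(1)
        time = np.array([2.0, 2, 2, 5, 5, 8, 9, 9, 12, 15])
        event = np.array([1, 1, 0, 1, 1, 1, 0, 1, 1, 0])
        x = rng.normal(size=10)
        for beta in (-1.0, 0.0, 0.7):
            mine = cox_log_partial_likelihood(beta, time, event, x)
            oracle = partial_likelihood_oracle(beta, time, event, x)
            assert mine == pytest.approx(oracle, abs=1e-10)

    def test_agrees_with_lifelines(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(2)
        n = 80
        x = rng.normal(size=n)
        time = np.round(rng.exponential(np.exp(-0.5 * x)) * 100) + 1  # heavy ties
        event = rng.integers(0, 2, n)
        event[:5] = 1
        res = cox_fit_univariate(time, event, x)
        cph = CoxPHFitter()
        cph.fit(
            pd.DataFrame({"T": time, "E": event, "x": x}),
            duration_col="T", event_col="E",
        )
        assert res.beta == pytest.approx(cph.params_["x"], abs=1e-5)
        assert res.se == pytest.approx(cph.standard_errors_["x"], abs=1e-5)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        time = rng.exponential(10, 30)
        event = rng.integers(0, 2, 30)
        event[:5] = 1
        x = rng.normal(size=30)
        b1 = cox_fit_univariate(time, event, x).beta
        b2 = cox_fit_univariate(time, event, 10 * x).beta
        assert b2 == pytest.approx(b1 / 10, abs=1e-8)

    def test_perfect_separation_capped_and_flagged(self):
        time = np.concatenate([np.arange(1, 11), np.arange(100, 110)])
        event = np.ones(20, dtype=int)
        x = np.repeat([1.0, 0.0], 10)  # high covariate => always dies first
        res = cox_fit_univariate(time, event, x)
        assert res.monotone
        assert abs(res.beta) == pytest.approx(15.0)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit_univariate(np.arange(1.0, 11), np.ones(10, int), np.ones(10))

    def test_hazard_coefficient_recovered(self, recovery_stats):
        betas = [s["beta_activity"] for s in recovery_stats]
        assert abs(np.mean(betas) - 0.8) <= 0.15


class TestKM:
    def test_no_events_flat_curve(self):
        curve = km_curve([1.0, 2.0, 3.0], [0, 0, 0])
        assert curve.times.size == 0  # no event times, S(t) = 1 throughout

    def test_all_events_stepwise(self):
        curve = km_curve([1.0, 2.0, 3.0], [1, 1, 1])
        assert np.allclose(curve.survival, [2 / 3, 1 / 3, 0.0])

    def test_censoring_between_events(self):
        curve = km_curve([1.0, 2.0, 3.0], [1, 0, 1])
        assert np.allclose(curve.survival, [2 / 3, 0.0])

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(4)
        time = np.ceil(rng.exponential(10, 50))
        event = rng.integers(0, 2, 50)
        curve = km_curve(time, event)
        kmf = KaplanMeierFitter().fit(time, event)
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(kmf.predict(t), abs=1e-10)

    def test_pooled_curve_between_group_envelopes(self):
        rng = np.random.default_rng(5)
        t1 = rng.exponential(5, 40)
        t2 = rng.exponential(15, 40)
        e = np.ones(40, dtype=int)
        pooled = km_curve(np.concatenate([t1, t2]), np.concatenate([e, e]))
        c1 = km_curve(t1, e)
        c2 = km_curve(t2, e)

        def step_value(curve, t):
            idx = np.searchsorted(curve.times, t, side="right") - 1
            return 1.0 if idx < 0 else curve.survival[idx]

        for t, s in zip(pooled.times, pooled.survival):
            lo = min(step_value(c1, t), step_value(c2, t))
            hi = max(step_value(c1, t), step_value(c2, t))
            assert lo - 1e-12 <= s <= hi + 1e-12

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_curve([-1.0, 2.0], [1, 1])


class TestLogrank:
    def test_identical_groups_zero(self):
        time = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        event = np.array([1, 0, 1, 1, 1, 0, 1, 1])
        groups = np.repeat(["a", "b"], 4)
        chi2, df, p = logrank_test(time, event, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_evaluation_two_groups(self):
        """{1,2} vs {3,4}, all events: O-E and variance summed by hand over
        the four event times."""
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.ones(4, dtype=int)
        groups = np.array(["a", "a", "b", "b"])
        # t=1: n=4, n_a=2, d=1, E_a=1/2, V=(1*3/3)*(2*4-4)/16 -> 1/4
        # t=2: n=3, n_a=1, E_a=1/3, V=2/9;  t=3: n=2, n_a=0; t=4: n=1, n_a=0
        o_minus_e = (1 - 0.5) + (1 - 1 / 3) + 0.0 + 0.0
        var = 0.25 + 2 / 9
        chi2, df, p = logrank_test(time, event, groups)
        assert df == 1
        assert chi2 == pytest.approx(o_minus_e**2 / var, abs=1e-12)

    def test_matches_lifelines_multigroup(self):
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(6)
        n = 90
        time = np.ceil(rng.exponential(10, n))
        event = rng.integers(0, 2, n)
        groups = rng.integers(0, 3, n)
        chi2, df, p = logrank_test(time, event, groups)
        ref = multivariate_logrank_test(time, groups, event)
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-8)
        assert p == pytest.approx(ref.p_value, abs=1e-10)

    def test_type_one_error_calibrated(self, logrank_type1):
        assert 0.04 <= logrank_type1 <= 0.06

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [1, 1], ["a", "a"])


class TestCutpoint:
    def test_separating_gap_found(self):
        rng = np.random.default_rng(7)
        n = 40
        score = np.concatenate([rng.uniform(0, 1, 20), rng.uniform(3, 4, 20)])
        time = np.concatenate([rng.exponential(2, 20), rng.exponential(30, 20)])
        event = np.ones(n, dtype=int)
        res = optimal_cutpoint(score, time, event)
        assert 1.0 < res.cutoff < 3.0

    def test_matches_exhaustive_scan_with_independent_logrank(self):
        """Every feasible split re-scored with lifelines' log-rank; the
        selected cutoff maximizes that independent statistic too."""
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(8)
        n = 20
        score = rng.normal(size=n)
        time = rng.exponential(10, n)
        event = rng.integers(0, 2, n)
        event[:4] = 1
        res = optimal_cutpoint(score, time, event, minprop=0.1)
        uniq = np.unique(score)
        best_stat, best_cut = -np.inf, None
        for c in (uniq[:-1] + uniq[1:]) / 2:
            high = score > c
            if high.sum() < 2 or (~high).sum() < 2:
                continue
            ref = ll_logrank(time[high], time[~high], event[high], event[~high])
            stat = np.sqrt(ref.test_statistic)
            if stat > best_stat + 1e-12:
                best_stat, best_cut = stat, c
        assert res.cutoff == pytest.approx(best_cut)
        assert res.statistic == pytest.approx(best_stat, abs=1e-8)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        score = rng.normal(size=30)
        time = rng.exponential(10, 30)
        event = rng.integers(0, 2, 30)
        event[:5] = 1
        a = optimal_cutpoint(score, time, event)
        b = optimal_cutpoint(np.exp(score), time, event)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-10)
        assert (score > a.cutoff).sum() == (np.exp(score) > b.cutoff).sum()

    def test_constant_score_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            optimal_cutpoint(np.ones(20), np.arange(1.0, 21), np.ones(20, int))

    def test_minprop_respected(self):
        rng = np.random.default_rng(10)
        score = rng.normal(size=50)
        time = rng.exponential(10, 50)
        event = np.ones(50, dtype=int)
        res = optimal_cutpoint(score, time, event, minprop=0.2)
        n_high = (score > res.cutoff).sum()
        assert 10 <= n_high <= 40

    def test_selection_inflates_null_statistic(self):
        """Under the null, the maximally selected statistic exceeds the
        nominal chi-square(1) 95% quantile far more often than 5% — hence
        the cutpoint p-value is descriptive only."""
        rng = np.random.default_rng(11)
        crit = stats.chi2.ppf(0.95, 1)
        exceed = 0
        reps = 2000
        for _ in range(reps):
            n = 30
            score = rng.normal(size=n)
            time = rng.exponential(10, n)
            event = rng.integers(0, 2, n)
            event[:3] = 1
            res = optimal_cutpoint(score, time, event, minprop=0.1)
            exceed += res.statistic**2 > crit
        assert exceed / reps >= 0.15


class TestChiSquare:
    def test_closed_form_2x2(self):
        chi2, df, p = chi_square_2xk([[20, 30], [30, 20]])
        # n(ad-bc)^2 / (row and column products) = 100*(400-900)^2/(50*50*50*50)
        assert chi2 == pytest.approx(4.0, abs=1e-12)
        assert df == 1

    def test_proportional_table_zero(self):
        chi2, _, p = chi_square_2xk([[10, 20], [20, 40]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zero_column_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2xk([[5, 0], [7, 0]])

    def test_yates_correction_reduces_statistic(self):
        plain, _, _ = chi_square_2xk([[20, 30], [30, 20]])
        yates, _, _ = chi_square_2xk([[20, 30], [30, 20]], yates=True)
        assert yates < plain
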