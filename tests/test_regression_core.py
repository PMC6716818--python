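"""Regression engines against independent oracles: normal equations for
OLS, explicit partial-likelihood enumeration and lifelines for Cox,
null-calibration simulations for Wald p-values and the Schoenfeld test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.optimize import minimize_scalar

from vitdmr.exceptions import InvalidParameterError, SingularDesignError
from vitdmr.regression_core import (
    fit_cox,
    fit_ols,
    quartile_cox,
    schoenfeld_test,
)


class TestOls:
    def test_exact_fit_zero_se(self):
        x = np.arange(1.0, 6.0)
        fit = fit_ols(2 * x, pd.DataFrame({"x": x}))
        assert fit.beta("x") == pytest.approx(2.0, abs=1e-12)
        assert fit.se("x") == pytest.approx(0.0, abs=1e-10)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_normal_equations_oracle(self, seed):
        # independent oracle: solve (X'X) b = X'y directly
        rng = np.random.default_rng(seed)
        n, p = 12, 2
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        fit = fit_ols(y, pd.DataFrame(X, columns=["a", "b"]))
        Xi = np.column_stack([np.ones(n), X])
        b_oracle = np.linalg.solve(Xi.T @ Xi, Xi.T @ y)
        got = fit.terms["beta"].to_numpy()
        assert np.allclose(got, b_oracle, atol=1e-10)
        resid = y - Xi @ b_oracle
        s2 = resid @ resid / (n - p - 1)
        se_oracle = np.sqrt(s2 * np.diag(np.linalg.inv(Xi.T @ Xi)))
        assert np.allclose(fit.terms["se"].to_numpy(), se_oracle, atol=1e-10)

    def test_rank_deficiency_raises(self):
        x = np.arange(5.0)
        with pytest.raises(SingularDesignError):
            fit_ols(x, pd.DataFrame({"a": x, "b": 2 * x}))


def _enumerated_partial_loglik(b, times, events, x):
    """Direct enumeration of the tie-free Cox partial likelihood."""
    ll = 0.0
    for i in range(len(times)):
        if not events[i]:
            continue
        risk = [j for j in range(len(times)) if times[j] >= times[i]]
        ll += b * x[i] - np.log(sum(np.exp(b * x[j]) for j in risk))
    return ll


class TestCox:
    # 6-subject hand dataset, single binary covariate, no ties
    T6 = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    E6 = np.array([1, 1, 0, 1, 1, 0])
    X6 = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 0.0])

    def test_matches_bruteforce_partial_likelihood(self):
        res = minimize_scalar(
            lambda b: -_enumerated_partial_loglik(b, self.T6, self.E6, self.X6),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10},
        )
        fit = fit_cox(self.T6, self.E6, pd.DataFrame({"x": self.X6}))
        assert fit.converged
        assert fit.log_hr("x") == pytest.approx(res.x, abs=1e-6)

    def test_matches_lifelines_on_simulated_data(self, rng):
        from lifelines import CoxPHFitter

        n = 400
        X = rng.normal(size=(n, 3))
        lp = X @ np.array([0.5, -0.3, 0.0])
        t = rng.exponential(np.exp(-lp))
        c = rng.exponential(2.0, n)
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        fit = fit_cox(time, event, df)
        ldf = df.assign(T=time, E=event)
        ll = CoxPHFitter().fit(ldf, "T", "E")
        assert np.allclose(
            fit.terms["log_hr"].to_numpy(), ll.params_.to_numpy(), atol=1e-5
        )
        assert np.allclose(fit.terms["se"].to_numpy(), ll.standard_errors_.to_numpy(), atol=1e-5)

    def test_breslow_equals_efron_without_ties(self, rng):
        n = 200
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.4 * x))
        e = (rng.random(n) < 0.7).astype(int)
        d = pd.DataFrame({"x": x})
        fe = fit_cox(t, e, d, ties="efron")
        fb = fit_cox(t, e, d, ties="breslow")
        assert fe.log_hr("x") == pytest.approx(fb.log_hr("x"), abs=1e-8)

    def test_efron_handles_tied_event_times(self, rng):
        # integer-rounded times force ties; Efron and Breslow should both
        # converge and differ slightly
        n = 150
        x = rng.normal(size=n)
        t = np.ceil(rng.exponential(np.exp(-0.5 * x)) * 4) / 4
        e = np.ones(n, dtype=int)
        fe = fit_cox(t, e, pd.DataFrame({"x": x}), ties="efron")
        fb = fit_cox(t, e, pd.DataFrame({"x": x}), ties="breslow")
        assert fe.converged and fb.converged
        assert fe.log_hr("x") != fb.log_hr("x")
        # Efron is closer to the tie-free truth than Breslow on average;
        # here just check both are in a sane neighbourhood of 0.5
        assert abs(fe.log_hr("x") - 0.5) < 0.35

    def test_independent_covariate_near_zero_large_n(self, rng):
        n = 20_000
        x = rng.normal(size=n)
        t = rng.exponential(1.0, n)
        e = (rng.random(n) < 0.5).astype(int)
        fit = fit_cox(t, e, pd.DataFrame({"x": x}))
        assert abs(fit.log_hr("x")) < 3 * fit.se("x")

    def test_no_events_rejected(self):
        with pytest.raises(InvalidParameterError):
            fit_cox([1.0, 2.0], [0, 0], pd.DataFrame({"x": [0.0, 1.0]}))

    def test_nonpositive_time_rejected(self):
        with pytest.raises(InvalidParameterError):
            fit_cox([0.0, 2.0], [1, 1], pd.DataFrame({"x": [0.0, 1.0]}))

    def test_separation_flagged_not_raised(self):
        # perfect separation: x=1 subjects all fail first
        t = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        e = np.array([1, 1, 1, 0, 0, 0])
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        fit = fit_cox(t, e, pd.DataFrame({"x": x}))
        assert not fit.converged

    def test_wald_pvalues_uniform_under_null(self):
        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(1000):
            n = 120
            x = rng.normal(size=n)
            t = rng.exponential(1.0, n)
            e = (rng.random(n) < 0.6).astype(int)
            pvals.append(fit_cox(t, e, pd.DataFrame({"x": x})).p("x"))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_ols_pvalues_uniform_under_null(self):
        rng = np.random.default_rng(100)
        pvals = []
        for _ in range(1000):
            x = rng.normal(size=60)
            y = rng.normal(size=60)
            pvals.append(fit_ols(y, pd.DataFrame({"x": x})).p("x"))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestQuartiles:
    def _survival(self, n, slope, rng):
        x = rng.normal(60, 25, n)
        t = rng.exponential(np.exp(-slope * (x - 60) / 25))
        c = np.full(n, 2.0)
        return x, np.minimum(t, c), (t <= c).astype(int)

    def test_monotone_effect_gives_monotone_quartile_hrs(self):
        rng = np.random.default_rng(3)
        x, t, e = self._survival(30_000, 0.5, rng)
        qa = quartile_cox(x, t, e)
        hrs = qa.table["hr"].to_numpy()
        assert hrs[0] == 1.0
        assert np.all(np.diff(hrs) > 0)
        assert qa.p_trend < 1e-6

    def test_null_exposure_trend_not_significant(self):
        rng = np.random.default_rng(4)
        x = rng.normal(60, 25, 5000)
        t = rng.exponential(1.0, 5000)
        e = (rng.random(5000) < 0.5).astype(int)
        qa = quartile_cox(x, t, e)
        assert np.allclose(qa.table["hr"].to_numpy(), 1.0, atol=0.35)
        assert qa.cutpoints.shape == (3,)

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(InvalidParameterError):
            quartile_cox([1.0, 1.0, 2.0], [1, 2, 3], [1, 1, 1])


class TestSchoenfeld:
    def test_pvalues_uniform_under_proportional_hazards(self):
        rng = np.random.default_rng(21)
        pvals = []
        for _ in range(300):
            n = 200
            x = rng.normal(size=n)
            t = rng.exponential(np.exp(-0.3 * x))
            e = (rng.random(n) < 0.8).astype(int)
            d = pd.DataFrame({"x": x})
            fit = fit_cox(t, e, d)
            if fit.converged:
                pvals.append(schoenfeld_test(fit, t, e, d).table.loc["x", "p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_detects_nonproportional_hazards(self):
        # crossing hazards via group-specific Weibull shapes
        rng = np.random.default_rng(22)
        rejections = 0
        reps = 150
        for _ in range(reps):
            n = 300
            x = (rng.random(n) < 0.5).astype(float)
            shape = np.where(x == 1, 0.6, 1.6)
            t = rng.weibull(shape) * 1.0
            e = np.ones(n, dtype=int)
            t = np.maximum(t, 1e-6) + rng.uniform(0, 1e-9, n)  # break ties
            d = pd.DataFrame({"x": x})
            fit = fit_cox(t, e, d)
            if fit.converged and schoenfeld_test(fit, t, e, d).table.loc["x", "p"] < 0.05:
                rejections += 1
        assert rejections / reps > 0.5

    def test_single_event_rejected(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([0, 1, 0, 0])
        d = pd.DataFrame({"x": [0.0, 1.0, 0.5, -0.5]})
        fit = fit_cox(t, e, d)
        with pytest.raises(InvalidParameterError):
            schoenfeld_test(fit, t, e, d)
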