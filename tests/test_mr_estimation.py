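"""Causal estimators: Wald ratio arithmetic and delta SE, 2SLS identity
and sandwich SE, MR-Egger pleiotropy detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vitdmr.exceptions import InsufficientInstrumentsError, UndefinedRatioError
from vitdmr.mr_estimation import (
    GeneExposureEstimate,
    GeneOutcomeEstimate,
    egger_regression,
    snp_level_mr,
    two_stage_ls,
    wald_ratio,
)
from vitdmr.regression_core import fit_ols


def gx(beta, se=0.1):
    return GeneExposureEstimate(beta, se)


def gy(beta, se=0.01):
    return GeneOutcomeEstimate(beta, se)


class TestWaldRatio:
    def test_null_outcome_gives_unit_hr(self):
        w = wald_ratio(gy(0.0), gx(2.0))
        assert w.hr == pytest.approx(1.0)

    def test_hand_arithmetic_example(self):
        # 25 * (-0.01) / 2.0 = -0.125 -> HR = exp(-0.125)
        w = wald_ratio(gy(-0.01, se=0.004), gx(2.0, se=0.1))
        assert w.log_hr_per_25 == pytest.approx(-0.125)
        assert w.hr == pytest.approx(np.exp(-0.125), rel=1e-12)
        se_oracle = 25 * np.sqrt(0.004**2 / 4.0 + 0.01**2 * 0.1**2 / 2.0**4)
        assert w.se == pytest.approx(se_oracle, rel=1e-12)
        assert w.ci95[0] < w.hr < w.ci95[1]

    def test_zero_gene_exposure_rejected(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(gy(0.01), gx(0.0))

    def test_weak_instrument_flag(self):
        w = wald_ratio(gy(0.01), gx(1.0), first_stage_f=4.0)
        assert w.weak_instrument
        w2 = wald_ratio(gy(0.01), gx(1.0), first_stage_f=50.0)
        assert not w2.weak_instrument

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        by1=st.floats(-0.05, 0.05), by2=st.floats(-0.05, 0.05),
        bx=st.floats(0.5, 5.0),
    )
    def test_monotone_in_gene_outcome_effect(self, by1, by2, bx):
        w1 = wald_ratio(gy(by1), gx(bx))
        w2 = wald_ratio(gy(by2), gx(bx))
        # strict monotonicity holds on the log scale (exp may round for
        # subnormal effects)
        if by1 < by2:
            assert w1.log_hr_per_25 < w2.log_hr_per_25
        elif by1 > by2:
            assert w1.log_hr_per_25 > w2.log_hr_per_25

    def test_scale_equivariance(self):
        w25 = wald_ratio(gy(-0.004), gx(1.7), scale=25.0)
        w50 = wald_ratio(gy(-0.004), gx(1.7), scale=50.0)
        assert w50.log_hr_per_25 == pytest.approx(2 * w25.log_hr_per_25, rel=1e-12)
        assert w50.se == pytest.approx(2 * w25.se, rel=1e-12)


def _iv_data(rng, n=3000, beta_causal=0.02, conf=0.0):
    g = rng.binomial(2, 0.3, n).astype(float)
    u = rng.normal(size=n)
    x = 60 + 5.0 * g + conf * (-8.0) * u + rng.normal(0, 20, n)
    y = 3.0 + beta_causal * x + conf * 0.5 * u + rng.normal(0, 1, n)
    return g, x, y


class TestTwoStageLs:
    def test_single_instrument_identity_with_wald_ratio(self, rng):
        # just-identified 2SLS == reduced-form / first-stage ratio
        g, x, y = _iv_data(rng)
        first = fit_ols(x, pd.DataFrame({"g": g}))
        reduced = fit_ols(y, pd.DataFrame({"g": g}))
        ratio = 25.0 * reduced.beta("g") / first.beta("g")
        est = two_stage_ls(g, x, y)
        assert est.beta_per_25 == pytest.approx(ratio, abs=1e-8)

    def test_matches_statsmodels_iv2sls(self, rng):
        from statsmodels.sandbox.regression.gmm import IV2SLS

        g, x, y = _iv_data(rng, conf=1.0)
        cov = pd.DataFrame({"c": rng.normal(size=len(g))})
        est = two_stage_ls(g, x, y, covariates=cov)
        n = len(g)
        exog = np.column_stack([np.ones(n), cov["c"], x])
        instr = np.column_stack([np.ones(n), cov["c"], g])
        res = IV2SLS(y, exog, instrument=instr).fit()
        assert est.beta_per_25 == pytest.approx(25 * res.params[-1], rel=1e-8)
        assert est.se == pytest.approx(25 * res.bse[-1], rel=1e-6)

    def test_consistent_under_confounding_where_ols_biased(self, rng):
        g, x, y = _iv_data(rng, n=60_000, beta_causal=0.0, conf=1.0)
        est = two_stage_ls(g, x, y)
        ols = fit_ols(y, pd.DataFrame({"x": x}))
        assert abs(est.beta_per_25) < 3 * est.se
        # OLS picks up the confounded association
        assert abs(ols.beta("x") * 25) > 5 * (ols.se("x") * 25)

    def test_first_stage_f_reported(self, rng):
        g, x, y = _iv_data(rng, n=5000)
        est = two_stage_ls(g, x, y)
        assert est.first_stage_f > 10

    def test_useless_instrument_rejected(self, rng):
        n = 100
        g = np.zeros(n)
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        with pytest.raises(Exception):
            two_stage_ls(g, x, y)


class TestEgger:
    def test_proportional_effects_give_zero_intercept(self):
        bx = np.array([1.0, 2.0, 3.0, 4.0])
        tab = pd.DataFrame(
            {"beta_gx": bx, "beta_gy": -0.002 * bx, "se_gy": [0.01] * 4}
        )
        res = egger_regression(tab)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.slope == pytest.approx(-0.002, abs=1e-12)
        assert res.n_snps == 4

    def test_two_snps_rejected(self):
        tab = pd.DataFrame({"beta_gx": [1, 2], "beta_gy": [0, 0], "se_gy": [1, 1]})
        with pytest.raises(InsufficientInstrumentsError):
            egger_regression(tab)

    def test_directional_pleiotropy_detected(self, rng):
        # direct (non-exposure) outcome effects shared across the SNPs
        # shift the Egger intercept away from zero
        reps, hits = 60, 0
        for _ in range(reps):
            bx = np.array([1.0, 2.0, 3.0, 4.0])
            direct = 0.01 + rng.normal(0, 0.001, 4)  # directional pleiotropy
            by = -0.002 * bx + direct + rng.normal(0, 0.0005, 4)
            tab = pd.DataFrame({"beta_gx": bx, "beta_gy": by, "se_gy": [0.0005] * 4})
            if egger_regression(tab).intercept_p < 0.05:
                hits += 1
        assert hits / reps > 0.8

    def test_single_outlier_shifts_intercept_estimate(self):
        bx = np.array([1.0, 2.0, 3.0, 4.0])
        clean = pd.DataFrame(
            {"beta_gx": bx, "beta_gy": -0.002 * bx, "se_gy": [0.0005] * 4}
        )
        outlier = clean.assign(
            beta_gy=clean["beta_gy"] + np.array([0.02, 0.0, 0.0, 0.0])
        )
        assert abs(egger_regression(clean).intercept) < 1e-12
        assert abs(egger_regression(outlier).intercept) > 0.005


class TestSnpLevelMr:
    def test_single_snp_reduces_to_wald_ratio(self):
        e = gx(2.0, 0.1)
        o = gy(-0.01, 0.004)
        tab = snp_level_mr([("rs1", e, o)])
        w = wald_ratio(o, e)
        assert tab.loc[0, "hr"] == pytest.approx(w.hr)
        assert tab.loc[0, "se"] == pytest.approx(w.se)

    def test_empty_input_gives_empty_table(self):
        tab = snp_level_mr([])
        assert tab.empty
        assert "hr" in tab.columns

    def test_homogeneous_snps_agree_within_sampling_error(self, rng):
        # four instruments with a shared causal slope: per-SNP ratios
        # scatter around the same value
        from vitdmr.regression_core import fit_cox
        from vitdmr.synthetic_cohort import (
            EndpointSpec, ScenarioConfig, SnpDefinition, simulate_cohort,
        )

        cfg = ScenarioConfig(
            n_subjects=40_000,
            snps=[
                SnpDefinition("s1", "A", 0.45, 3.0, "synthesis"),
                SnpDefinition("s2", "A", 0.40, 3.5, "synthesis"),
                SnpDefinition("s3", "A", 0.28, 5.1, "transport"),
                SnpDefinition("s4", "A", 0.21, 4.0, "metabolism"),
            ],
            seed=77,
            endpoints={
                "ep": EndpointSpec(
                    causal_log_hr_per_25=-0.3, baseline_scale=40.0
                )
            },
        )
        cohort = simulate_cohort(cfg)
        rows = []
        for sid in ("s1", "s2", "s3", "s4"):
            d = pd.DataFrame({"g": cohort[f"dosage_{sid}"].astype(float)})
            f1 = fit_ols(cohort["exposure_25ohd"], d)
            c1 = fit_cox(cohort["time_ep"], cohort["event_ep"], d)
            rows.append(
                (sid, gx(f1.beta("g"), f1.se("g")), gy(c1.log_hr("g"), c1.se("g")))
            )
        tab = snp_level_mr(rows)
        z = (tab["log_hr_per_25"] - (-0.3)) / tab["se"]
        assert np.all(np.abs(z) < 4)
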