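"""End-to-end study replica: simulate cohorts, then run observational,
genetic, instrumental-variable, sensitivity and meta-analysis stages.

The report mirrors the shape of a two-cohort vitamin-D Mendelian-
randomisation study: observational Cox tables (continuous per 25 nmol/L
and by quartile), a per-SNP gene-exposure table with instrument
diagnostics, Wald-ratio and 2SLS causal tables, MR-Egger sensitivity
where >= 3 instruments exist, heterogeneity-gated pooling across
cohorts, and family-wise significance flags (Bonferroni alpha/m, with
p <= 0.05 above the corrected threshold labelled "suggestive").
"""

from __future__ import annotations

import logging
import time as _time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import meta_analysis as meta
from .exceptions import InvalidParameterError, VitdmrError
from .genetic_instruments import (
    build_allele_score,
    confounder_balance,
    hwe_test,
    instrument_strength,
)
from .mr_estimation import (
    GeneExposureEstimate,
    GeneOutcomeEstimate,
    egger_regression,
    snp_level_mr,
    two_stage_ls,
    wald_ratio,
)
from .regression_core import fit_cox, fit_ols, quartile_cox, schoenfeld_test
from .synthetic_cohort import generate_scenario

logger = logging.getLogger("vitdmr")

__all__ = [
    "CohortSpec",
    "PipelineConfig",
    "bonferroni_threshold",
    "classify_p",
    "convert_units",
    "build_design",
    "observational_stage",
    "genetic_stage",
    "mr_stage",
    "meta_stage",
    "run_pipeline",
    "COVARIATE_PROFILES",
]

COVARIATE_PROFILES = {
    # full multivariable adjustment for observational hazard models
    "ckb": ["age", "sex", "current_smoker", "current_drinker", "season",
            "region", "sbp", "low_physical_activity"],
    "cgps": ["age", "sex", "season", "sbp", "low_physical_activity",
             "current_smoker", "current_drinker"],
    # genetic analyses: age, sex, season, region only
    "genetic": ["age", "sex", "season", "region"],
}

# score/instrument sets per preset: the synthesis-SNP pair is the main
# instrument; the wider set feeds per-SNP MR and Egger sensitivity
PRESET_INSTRUMENTS = {
    "ckb_like": {
        "main_score": ["rs12785878", "rs10741657"],
        "all_snps": ["rs12785878", "rs10741657", "rs2282679", "rs6013897"],
    },
    "cgps_like": {
        "main_score": ["rs7944926", "rs10741657"],
        "all_snps": ["rs7944926", "rs10741657", "rs12794714"],
    },
    "causal": {
        "main_score": ["rs12785878", "rs10741657"],
        "all_snps": ["rs12785878", "rs10741657", "rs2282679", "rs6013897"],
    },
}


@dataclass
class CohortSpec:
    preset: str
    n: int
    seed: int
    covariate_profile: str = "ckb"
    overrides: dict | None = None


@dataclass
class PipelineConfig:
    cohorts: dict[str, CohortSpec]
    alpha_family: float = 0.05
    n_outcomes_for_bonferroni: int = 20
    i2_threshold: float = 0.25

    def __post_init__(self):
        if not (0.0 < self.alpha_family < 1.0):
            raise InvalidParameterError("alpha_family must lie in (0,1)")
        if self.n_outcomes_for_bonferroni < 1:
            raise InvalidParameterError("n_outcomes_for_bonferroni must be >= 1")


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha/m."""
    if m < 1:
        raise InvalidParameterError("number of outcomes m must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise InvalidParameterError("alpha must lie in (0,1)")
    return alpha / m


def classify_p(p: float, threshold: float, alpha: float = 0.05) -> str:
    """"significant" below the corrected threshold, "suggestive" when
    p <= alpha but above it, otherwise "null"."""
    if p < threshold:
        return "significant"
    if p <= alpha:
        return "suggestive"
    return "null"


_UNIT_FACTORS = {
    ("25ohd", "ng/ml", "nmol/L"): 2.496,
    ("tc", "mmol/L", "mg/dL"): 38.67,
    ("ldl", "mmol/L", "mg/dL"): 38.67,
    ("hdl", "mmol/L", "mg/dL"): 38.67,
    ("tg", "mmol/L", "mg/dL"): 88.57,
}


def convert_units(value: float, from_unit: str, to_unit: str, analyte: str = "25ohd") -> float:
    """Exact multiplicative unit conversion for supported analyte pairs.

    25(OH)D: 1 ng/ml = 2.496 nmol/L.  Cholesterol fractions use
    38.67 mg/dL per mmol/L and triglycerides 88.57.
    """
    if from_unit == to_unit:
        return value
    key = (analyte, from_unit, to_unit)
    if key in _UNIT_FACTORS:
        return value * _UNIT_FACTORS[key]
    inv = (analyte, to_unit, from_unit)
    if inv in _UNIT_FACTORS:
        return value / _UNIT_FACTORS[inv]
    raise InvalidParameterError(
        f"unsupported conversion {from_unit!r} -> {to_unit!r} for {analyte!r}"
    )


def build_design(cohort: pd.DataFrame, profile: str | list[str]) -> pd.DataFrame:
    """Design matrix for a named covariate profile; season and region
    enter as indicator contrasts against their first level."""
    names = COVARIATE_PROFILES[profile] if isinstance(profile, str) else profile
    blocks = []
    for name in names:
        if name in ("season", "region"):
            dummies = pd.get_dummies(
                cohort[name].astype(int), prefix=name, drop_first=True, dtype=float
            )
            blocks.append(dummies)
        else:
            blocks.append(cohort[[name]].astype(float))
    return pd.concat(blocks, axis=1)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _endpoints_of(cohort: pd.DataFrame) -> list[str]:
    return [c[len("time_"):] for c in cohort.columns if c.startswith("time_")]


def _lipids_of(cohort: pd.DataFrame) -> list[str]:
    return [c for c in ("tc", "ldl", "hdl", "tg", "apoa", "apob") if c in cohort.columns]


def observational_stage(cohort: pd.DataFrame, profile: str = "ckb") -> dict:
    """Continuous (per 25 nmol/L) and quartile Cox models per endpoint,
    a Schoenfeld proportional-hazards check, and lipid OLS."""
    cov = build_design(cohort, profile)
    x25 = cohort["exposure_25ohd"] / 25.0
    out: dict = {"endpoints": {}, "lipids": {}}
    for ep in _endpoints_of(cohort):
        t, e = cohort[f"time_{ep}"], cohort[f"event_{ep}"]
        design = pd.concat([x25.rename("exposure_per25"), cov], axis=1)
        fit = fit_cox(t, e, design)
        sch = schoenfeld_test(fit, t, e, design)
        quart = quartile_cox(cohort["exposure_25ohd"], t, e, cov)
        b = fit.log_hr("exposure_per25")
        s = fit.se("exposure_per25")
        out["endpoints"][ep] = {
            "n_events": fit.n_events,
            "hr_per_25": float(np.exp(b)),
            "ci_low": float(np.exp(b - 1.96 * s)),
            "ci_high": float(np.exp(b + 1.96 * s)),
            "log_hr": b,
            "se": s,
            "p": fit.p("exposure_per25"),
            "schoenfeld_global_p": sch.global_p,
            "quartile_hrs": quart.table["hr"].to_dict(),
            "p_trend": quart.p_trend,
        }
    for lip in _lipids_of(cohort):
        design = pd.concat([x25.rename("exposure_per25"), cov], axis=1)
        fit = fit_ols(cohort[lip], design)
        out["lipids"][lip] = {
            "beta_per_25": fit.beta("exposure_per25"),
            "se": fit.se("exposure_per25"),
            "p": fit.p("exposure_per25"),
        }
    return out


def genetic_stage(cohort: pd.DataFrame, instruments: dict, profile: str = "genetic") -> dict:
    """Per-allele gene-exposure effects, score effects with F-statistics,
    Hardy-Weinberg checks, and the confounder-balance table."""
    cov = build_design(cohort, profile)
    exposure = cohort["exposure_25ohd"]
    balance_covs = ["age", "sex", "current_smoker", "current_drinker",
                    "season", "region", "sbp", "low_physical_activity", "bmi"]
    out: dict = {"per_snp": {}, "scores": {}, "confounder_balance": {}}
    for snp in instruments["all_snps"]:
        g = cohort[f"dosage_{snp}"]
        design = pd.concat([g.rename("score").astype(float), cov], axis=1)
        fit = fit_ols(exposure, design)
        counts = [int((g == k).sum()) for k in (0, 1, 2)]
        chi2, p_hwe = hwe_test(counts)
        out["per_snp"][snp] = {
            "beta": fit.beta("score"),
            "se": fit.se("score"),
            "p": fit.p("score"),
            "F": instrument_strength(fit).f_statistic,
            "hwe_chi2": chi2,
            "hwe_p": p_hwe,
        }
        out["confounder_balance"][snp] = confounder_balance(
            g, cohort[balance_covs]
        )
    dosages = cohort[[f"dosage_{s}" for s in instruments["all_snps"]]].rename(
        columns=lambda c: c[len("dosage_"):]
    )
    for label, snps in (
        ("main_score", instruments["main_score"]),
        ("all_snp_score", instruments["all_snps"]),
    ):
        score = build_allele_score(dosages, snps)
        design = pd.concat([score.values.rename("score"), cov], axis=1)
        fit = fit_ols(exposure, design)
        strength = instrument_strength(fit)
        out["scores"][label] = {
            "snps": snps,
            "beta": fit.beta("score"),
            "se": fit.se("score"),
            "F": strength.f_statistic,
            "weak": strength.weak,
        }
    return out


def mr_stage(cohort: pd.DataFrame, instruments: dict, profile: str = "genetic") -> dict:
    """Instrumental-variable estimates: Wald ratios for survival
    endpoints, 2SLS for lipids, per-SNP ratios and MR-Egger."""
    cov = build_design(cohort, profile)
    exposure = cohort["exposure_25ohd"]
    dosages = cohort[[f"dosage_{s}" for s in instruments["all_snps"]]].rename(
        columns=lambda c: c[len("dosage_"):]
    )
    score = build_allele_score(dosages, instruments["main_score"]).values

    first_design = pd.concat([score.rename("score"), cov], axis=1)
    first = fit_ols(exposure, first_design)
    strength = instrument_strength(first)
    gx = GeneExposureEstimate(first.beta("score"), first.se("score"), n=first.n)

    out: dict = {
        "first_stage": {
            "beta_gx": gx.beta_gx, "se_gx": gx.se_gx,
            "F": strength.f_statistic, "weak": strength.weak,
        },
        "endpoints": {}, "lipids": {}, "per_snp": {}, "egger": {},
    }
    for ep in _endpoints_of(cohort):
        t, e = cohort[f"time_{ep}"], cohort[f"event_{ep}"]
        cox = fit_cox(t, e, first_design)
        gy = GeneOutcomeEstimate(cox.log_hr("score"), cox.se("score"), outcome=ep)
        w = wald_ratio(gy, gx, first_stage_f=strength.f_statistic)
        out["endpoints"][ep] = {
            "hr_per_25": w.hr, "ci_low": w.ci95[0], "ci_high": w.ci95[1],
            "log_hr": w.log_hr_per_25, "se": w.se,
            "p": float(2 * _norm_sf(abs(w.log_hr_per_25 / w.se))),
            "weak_instrument": w.weak_instrument,
        }
        # per-SNP ratios + Egger sensitivity for this endpoint
        per_snp = []
        for snp in instruments["all_snps"]:
            g = cohort[f"dosage_{snp}"].astype(float)
            d1 = pd.concat([g.rename("score"), cov], axis=1)
            f1 = fit_ols(exposure, d1)
            c1 = fit_cox(t, e, d1)
            per_snp.append(
                (snp,
                 GeneExposureEstimate(f1.beta("score"), f1.se("score"), n=f1.n),
                 GeneOutcomeEstimate(c1.log_hr("score"), c1.se("score"), outcome=ep))
            )
        table = snp_level_mr(per_snp)
        out["per_snp"][ep] = table
        if len(table) >= 3:
            eg_inputs = pd.DataFrame(
                {
                    "beta_gx": [est.beta_gx for _, est, _ in per_snp],
                    "beta_gy": [est.beta_gy for _, _, est in per_snp],
                    "se_gy": [est.se_gy for _, _, est in per_snp],
                }
            )
            eg = egger_regression(eg_inputs)
            out["egger"][ep] = {
                "slope_per_nmol": eg.slope,
                "intercept": eg.intercept,
                "intercept_se": eg.intercept_se,
                "intercept_p": eg.intercept_p,
                "n_snps": eg.n_snps,
            }
    for lip in _lipids_of(cohort):
        est = two_stage_ls(score.to_numpy(), exposure, cohort[lip], covariates=cov)
        out["lipids"][lip] = {
            "beta_per_25": est.beta_per_25, "se": est.se,
            "ci_low": est.ci95[0], "ci_high": est.ci95[1],
            "p": float(2 * _norm_sf(abs(est.beta_per_25 / est.se))),
            "first_stage_F": est.first_stage_f,
        }
    return out


def _norm_sf(z: float) -> float:
    from scipy.stats import norm

    return float(norm.sf(z))


def meta_stage(cohort_reports: dict, i2_threshold: float = 0.25) -> dict:
    """Pool IV estimates across cohorts for every shared outcome.

    Hazard ratios are pooled on the log scale and exponentiated; the
    fixed/random choice follows the I^2 > threshold rule.
    """
    names = list(cohort_reports)
    if len(names) < 2:
        return {}
    out: dict = {"endpoints": {}, "lipids": {}}
    shared_eps = set.intersection(
        *(set(r["mr"]["endpoints"]) for r in cohort_reports.values())
    )
    for ep in sorted(shared_eps):
        est = [cohort_reports[c]["mr"]["endpoints"][ep]["log_hr"] for c in names]
        ses = [cohort_reports[c]["mr"]["endpoints"][ep]["se"] for c in names]
        res = meta.pool(est, ses, i2_threshold=i2_threshold)
        out["endpoints"][ep] = {
            "hr_per_25": float(np.exp(res.estimate)),
            "ci_low": float(np.exp(res.ci95[0])),
            "ci_high": float(np.exp(res.ci95[1])),
            "log_hr": res.estimate, "se": res.se,
            "Q": res.q, "i2": res.i2, "tau2": res.tau2, "model": res.model,
            "p": float(2 * _norm_sf(abs(res.estimate / res.se))),
        }
    shared_lip = set.intersection(
        *(set(r["mr"]["lipids"]) for r in cohort_reports.values())
    )
    for lip in sorted(shared_lip):
        est = [cohort_reports[c]["mr"]["lipids"][lip]["beta_per_25"] for c in names]
        ses = [cohort_reports[c]["mr"]["lipids"][lip]["se"] for c in names]
        res = meta.pool(est, ses, i2_threshold=i2_threshold)
        out["lipids"][lip] = {
            "beta_per_25": res.estimate, "se": res.se,
            "ci_low": res.ci95[0], "ci_high": res.ci95[1],
            "Q": res.q, "i2": res.i2, "tau2": res.tau2, "model": res.model,
            "p": float(2 * _norm_sf(abs(res.estimate / res.se))),
        }
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage for every cohort and pool across cohorts.

    Deterministic given the per-cohort seeds; the report carries a
    provenance block (preset, seed, n) per cohort and family-wise
    significance flags on the IV results.
    """
    threshold = bonferroni_threshold(
        config.alpha_family, config.n_outcomes_for_bonferroni
    )
    report: dict = {
        "provenance": {},
        "bonferroni": {
            "alpha": config.alpha_family,
            "m": config.n_outcomes_for_bonferroni,
            "threshold": threshold,
        },
        "cohorts": {},
    }
    cohort_reports: dict = {}
    for name, spec in config.cohorts.items():
        stage = "simulate"
        try:
            t0 = _time.perf_counter()
            cohort = generate_scenario(
                spec.preset, spec.n, spec.seed, overrides=spec.overrides
            )
            instruments = PRESET_INSTRUMENTS[spec.preset]
            logger.info("cohort %s simulated in %.1fs", name, _time.perf_counter() - t0)
            stage = "observational"
            obs = observational_stage(cohort, spec.covariate_profile)
            stage = "genetic"
            gen = genetic_stage(cohort, instruments)
            stage = "mr"
            mr = mr_stage(cohort, instruments)
        except Exception as err:
            raise VitdmrError(f"stage {stage!r} failed for cohort {name!r}: {err}") from err
        for ep, row in mr["endpoints"].items():
            row["classification"] = classify_p(row["p"], threshold, config.alpha_family)
        for lip, row in mr["lipids"].items():
            row["classification"] = classify_p(row["p"], threshold, config.alpha_family)
        cohort_reports[name] = {"observational": obs, "genetic": gen, "mr": mr}
        report["provenance"][name] = {
            "preset": spec.preset,
            "seed": spec.seed,
            "n": spec.n,
            "covariate_profile": spec.covariate_profile,
        }
    try:
        pooled = meta_stage(cohort_reports, config.i2_threshold)
    except Exception as err:  # pragma: no cover - defensive
        raise VitdmrError(f"stage 'meta' failed: {err}") from err
    for section in pooled.values():
        for row in section.values():
            row["classification"] = classify_p(row["p"], threshold, config.alpha_family)
    report["cohorts"] = cohort_reports
    report["meta"] = pooled
    return report
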