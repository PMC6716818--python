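"""Synthetic biobank-style cohorts with a known genetic architecture.

Generates subject-level tables that emulate the structure of large
vitamin-D Mendelian-randomisation studies: 2-4 SNPs in Hardy-Weinberg
proportions whose raising alleles shift plasma 25(OH)D by a fraction of
a nmol/L up to ~5 nmol/L per allele, a latent "unhealthy lifestyle"
confounder that lowers 25(OH)D while raising mortality hazard and
adverse lipid levels, a seasonal sinusoid in 25(OH)D, Weibull
proportional-hazards event times with administrative plus random
censoring, and a continuous lipid panel.

Because the causal effect of 25(OH)D on every endpoint is a configured
parameter (zero in the observational presets), every downstream
estimator can be validated against a known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .exceptions import AlignmentError, InvalidParameterError

__all__ = [
    "SnpDefinition",
    "EndpointSpec",
    "LipidSpec",
    "ScenarioConfig",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_exposure",
    "simulate_survival",
    "simulate_lipids",
    "simulate_cohort",
    "generate_scenario",
    "load_preset",
    "available_presets",
    "unweighted_score_coefficient",
    "calibrate_score_betas",
]

SNP_ROLES = ("synthesis", "transport", "metabolism")

# log-hazard contributions of measured covariates (per unit, centred),
# shared across endpoints; values give a realistic mortality gradient
# with age, male sex, smoking and blood pressure.
DEFAULT_COVARIATE_LOG_HR = {
    "age": 0.085,  # per year
    "sex": -0.45,  # sex=1 is female
    "current_smoker": 0.35,
    "sbp": 0.008,  # per mmHg
    "low_physical_activity": 0.20,
}


@dataclass
class SnpDefinition:
    """One biallelic instrument SNP: the raising allele increases 25(OH)D."""

    snp_id: str
    raising_allele: str
    allele_freq: float
    beta_exposure: float  # nmol/L per raising allele
    role: str = "synthesis"

    def __post_init__(self):
        if not (0.0 < self.allele_freq < 1.0):
            raise InvalidParameterError(
                f"{self.snp_id}: allele frequency must lie strictly in (0,1), "
                f"got {self.allele_freq}"
            )
        if not np.isfinite(self.beta_exposure):
            raise InvalidParameterError(f"{self.snp_id}: beta_exposure must be finite")
        if self.role not in SNP_ROLES:
            raise InvalidParameterError(
                f"{self.snp_id}: role must be one of {SNP_ROLES}, got {self.role!r}"
            )


@dataclass
class EndpointSpec:
    """Survival endpoint: Weibull baseline, causal and confounder effects."""

    causal_log_hr_per_25: float = 0.0  # log HR per 25 nmol/L 25(OH)D
    confounder_log_hr_per_sd: float = 0.0  # log HR per SD of latent U
    baseline_shape: float = 1.0  # Weibull shape (1 = exponential)
    baseline_scale: float = 110.0  # years

    def __post_init__(self):
        if self.baseline_shape <= 0 or self.baseline_scale <= 0:
            raise InvalidParameterError("Weibull shape and scale must be positive")


@dataclass
class LipidSpec:
    mean: float
    sd: float
    causal_per_25: float = 0.0  # outcome units per 25 nmol/L 25(OH)D
    confounder_per_sd: float = 0.0

    def __post_init__(self):
        if self.sd < 0:
            raise InvalidParameterError("lipid noise SD must be nonnegative")


@dataclass
class ScenarioConfig:
    """Full recipe for one cohort; the seed determines every column."""

    n_subjects: int
    snps: list[SnpDefinition]
    seed: int = 0
    ld_r2: float = 0.0
    proxy_pair: tuple[str, str] | None = None
    exposure_mean: float = 63.7  # nmol/L
    noise_sd: float = 24.0  # nmol/L
    season_amplitude: float = 10.0  # nmol/L
    confounder_exposure: float = 0.0  # nmol/L per SD of latent U
    endpoints: dict[str, EndpointSpec] = field(default_factory=dict)
    lipids: dict[str, LipidSpec] = field(default_factory=dict)
    admin_censor_years: float = 12.0
    random_censor_rate: float = 0.005  # per year
    covariate_log_hr: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_LOG_HR)
    )
    preset: str | None = None

    def __post_init__(self):
        if self.n_subjects < 1:
            raise InvalidParameterError("n_subjects must be >= 1")
        if not (0.0 <= self.ld_r2 <= 1.0):
            raise InvalidParameterError("ld_r2 must lie in [0,1]")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be nonnegative")
        if self.admin_censor_years <= 0:
            raise InvalidParameterError("administrative censoring time must be > 0")
        if self.random_censor_rate < 0:
            raise InvalidParameterError("random censoring rate must be >= 0")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(
    n: int,
    snps: list[SnpDefinition],
    ld_r2: float = 0.0,
    proxy_pair: tuple[str, str] | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw allele dosages (0/1/2) under Hardy-Weinberg proportions.

    If ``ld_r2 > 0`` the second SNP of ``proxy_pair`` is generated from
    the first by a copy-with-error haplotype scheme: each of its two
    haplotype alleles copies the partner's allele with probability
    sqrt(ld_r2), otherwise it is drawn fresh at its own frequency, so
    the squared dosage correlation approaches ``ld_r2`` (exact in
    expectation when the pair shares an allele frequency).
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if not (0.0 <= ld_r2 <= 1.0):
        raise InvalidParameterError("ld_r2 must lie in [0,1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = [s.snp_id for s in snps]
    if len(set(ids)) != len(ids):
        raise InvalidParameterError("duplicate snp_id in SNP list")
    if ld_r2 > 0 and proxy_pair is None:
        if len(snps) < 2:
            raise InvalidParameterError("ld_r2 > 0 requires at least two SNPs")
        proxy_pair = (ids[0], ids[1])

    hap = {}
    out = {}
    for snp in snps:
        p = snp.allele_freq
        if ld_r2 > 0 and proxy_pair is not None and snp.snp_id == proxy_pair[1]:
            src = hap.get(proxy_pair[0])
            if src is None:
                raise InvalidParameterError(
                    f"proxy pair partner {proxy_pair[0]!r} must precede "
                    f"{proxy_pair[1]!r} in the SNP list"
                )
            c = float(np.sqrt(ld_r2))
            copy = rng.random((n, 2)) < c
            fresh = (rng.random((n, 2)) < p).astype(np.int8)
            h = np.where(copy, src, fresh)
        else:
            h = (rng.random((n, 2)) < p).astype(np.int8)
        hap[snp.snp_id] = h
        out[snp.snp_id] = h.sum(axis=1).astype(np.int8)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# covariates and exposure
# ---------------------------------------------------------------------------


def simulate_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Baseline covariate roster of a middle-aged biobank cohort."""
    age = np.clip(rng.normal(51.4, 10.6, n), 30.0, 79.0)
    sex = (rng.random(n) < 0.61).astype(np.int8)  # 1 = female
    smoker = (rng.random(n) < 0.37).astype(np.int8)
    drinker = (rng.random(n) < 0.54).astype(np.int8)
    day = rng.integers(1, 366, n)
    season = np.minimum((day - 1) // 92 + 1, 4).astype(np.int8)  # 4 levels
    region = rng.integers(0, 5, n).astype(np.int8)
    sbp = np.clip(rng.normal(131.2, 21.3, n), 80.0, 230.0)
    lpa = (rng.random(n) < 0.18).astype(np.int8)
    bmi = np.clip(rng.normal(23.7, 3.4, n), 14.0, 45.0)
    return pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "current_smoker": smoker,
            "current_drinker": drinker,
            "day_of_year": day,
            "season": season,
            "region": region,
            "sbp": sbp,
            "low_physical_activity": lpa,
            "bmi": bmi,
        }
    )


def simulate_exposure(
    dosages: pd.DataFrame,
    covariates: pd.DataFrame,
    config: ScenarioConfig,
    latent_u: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Plasma 25(OH)D from genetics, season, confounding and noise.

    Genetic contributions are centred at their expectation so the cohort
    mean stays at ``config.exposure_mean``; the seasonal term is a
    sinusoid over day of year (summer peak) later analysed as a 4-level
    category.
    """
    if len(dosages) != len(covariates) or len(dosages) != len(latent_u):
        raise AlignmentError("dosages, covariates and latent_u must be aligned")
    n = len(dosages)
    x = np.full(n, config.exposure_mean, dtype=float)
    for snp in config.snps:
        if snp.snp_id not in dosages.columns:
            raise AlignmentError(f"dosage column missing for {snp.snp_id}")
        g = dosages[snp.snp_id].to_numpy(dtype=float)
        x += snp.beta_exposure * (g - 2.0 * snp.allele_freq)
    day = covariates["day_of_year"].to_numpy(dtype=float)
    # peak late July (day ~205) as for northern-hemisphere sun exposure
    x += config.season_amplitude * np.cos(2.0 * np.pi * (day - 205.0) / 365.25)
    x += config.confounder_exposure * latent_u
    if config.noise_sd > 0:
        x += rng.normal(0.0, config.noise_sd, n)
    return x


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------


def _linear_predictor(
    exposure: np.ndarray,
    covariates: pd.DataFrame,
    latent_u: np.ndarray,
    config: ScenarioConfig,
    spec: EndpointSpec,
) -> np.ndarray:
    lp = spec.causal_log_hr_per_25 * exposure / 25.0
    lp = lp + spec.confounder_log_hr_per_sd * latent_u
    for name, eff in config.covariate_log_hr.items():
        lp = lp + eff * covariates[name].to_numpy(dtype=float)
    return lp - lp.mean()  # centring fixes the marginal event rate


def simulate_survival(
    exposure: np.ndarray,
    covariates: pd.DataFrame,
    latent_u: np.ndarray,
    config: ScenarioConfig,
    spec: EndpointSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Weibull proportional-hazards event times with censoring.

    T = scale * (E * exp(-lp))**(1/shape) with E ~ Exp(1), so the hazard
    is multiplied by exp(lp); follow-up is the minimum of the event
    time, the administrative horizon and an exponential random-censoring
    time.
    """
    if len(exposure) != len(covariates) or len(exposure) != len(latent_u):
        raise AlignmentError("exposure, covariates and latent_u must be aligned")
    n = len(exposure)
    lp = _linear_predictor(exposure, covariates, latent_u, config, spec)
    e = rng.exponential(1.0, n)
    t_event = spec.baseline_scale * (e * np.exp(-lp)) ** (1.0 / spec.baseline_shape)
    censor = np.full(n, config.admin_censor_years)
    if config.random_censor_rate > 0:
        censor = np.minimum(
            censor, rng.exponential(1.0 / config.random_censor_rate, n)
        )
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(np.int8)
    # follow-up must stay positive for the Cox engine
    time = np.maximum(time, 1e-8)
    return time, event


def simulate_lipids(
    exposure: np.ndarray,
    covariates: pd.DataFrame,
    latent_u: np.ndarray,
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Continuous lipid panel with causal and confounded components."""
    if len(exposure) != len(covariates) or len(exposure) != len(latent_u):
        raise AlignmentError("exposure, covariates and latent_u must be aligned")
    n = len(exposure)
    xc = (exposure - exposure.mean()) / 25.0
    out = {}
    for name, spec in config.lipids.items():
        y = spec.mean + spec.causal_per_25 * xc + spec.confounder_per_sd * latent_u
        if spec.sd > 0:
            y = y + rng.normal(0.0, spec.sd, n)
        out[name] = y
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# full cohorts and presets
# ---------------------------------------------------------------------------


def simulate_cohort(config: ScenarioConfig) -> pd.DataFrame:
    """Generate the full subject table for one scenario.

    The ``latent_u`` column is the simulation-only confounder and is
    dropped by the cohort writer; every other column is fair game for
    analysis.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    dosages = simulate_genotypes(
        n, config.snps, config.ld_r2, config.proxy_pair, seed=rng
    )
    covariates = simulate_covariates(n, rng)
    latent_u = rng.normal(0.0, 1.0, n)
    exposure = simulate_exposure(dosages, covariates, config, latent_u, rng)

    parts = [
        pd.DataFrame({"subject_id": np.arange(1, n + 1)}),
        dosages.add_prefix("dosage_"),
        pd.DataFrame({"exposure_25ohd": exposure}),
        covariates,
        pd.DataFrame({"latent_u": latent_u}),
    ]
    for name, spec in config.endpoints.items():
        time, event = simulate_survival(
            exposure, covariates, latent_u, config, spec, rng
        )
        parts.append(pd.DataFrame({f"time_{name}": time, f"event_{name}": event}))
    if config.lipids:
        parts.append(simulate_lipids(exposure, covariates, latent_u, config, rng))
    cohort = pd.concat(parts, axis=1)
    cohort.attrs["scenario"] = {
        "preset": config.preset,
        "seed": int(config.seed),
        "n_subjects": int(n),
        "snps": [s.snp_id for s in config.snps],
        "endpoints": list(config.endpoints),
    }
    return cohort


def available_presets() -> list[str]:
    pkg = resources.files("vitdmr") / "presets"
    return sorted(p.name[:-5] for p in pkg.iterdir() if p.name.endswith(".yaml"))


def _deep_update(base: dict, overrides: dict) -> dict:
    for k, v in overrides.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


def load_preset(name: str, overrides: dict | None = None, **kwargs) -> ScenarioConfig:
    """Load a shipped scenario preset (``ckb_like``, ``cgps_like``,
    ``causal``) into a ScenarioConfig; keyword arguments override
    top-level config fields, ``overrides`` is deep-merged into the raw
    preset dictionary first."""
    path = resources.files("vitdmr") / "presets" / f"{name}.yaml"
    try:
        raw = yaml.safe_load(path.read_text())
    except FileNotFoundError:
        raise InvalidParameterError(
            f"unknown preset {name!r}; available: {available_presets()}"
        ) from None
    if overrides:
        _deep_update(raw, overrides)
    raw.update(kwargs)
    snps = [SnpDefinition(**s) for s in raw.pop("snps")]
    endpoints = {
        k: EndpointSpec(**v) for k, v in raw.pop("endpoints", {}).items()
    }
    lipids = {k: LipidSpec(**v) for k, v in raw.pop("lipids", {}).items()}
    proxy = raw.pop("proxy_pair", None)
    if proxy is not None:
        proxy = tuple(proxy)
    return ScenarioConfig(
        snps=snps, endpoints=endpoints, lipids=lipids, proxy_pair=proxy,
        preset=name, **raw,
    )


def generate_scenario(
    preset: str, n: int, seed: int, overrides: dict | None = None
) -> pd.DataFrame:
    """One-call cohort generation from a named preset."""
    config = load_preset(preset, overrides=overrides, n_subjects=n, seed=seed)
    return simulate_cohort(config)


# ---------------------------------------------------------------------------
# analytic helpers for score-level effects
# ---------------------------------------------------------------------------


def unweighted_score_coefficient(betas, freqs) -> float:
    """Population OLS coefficient of exposure on the unweighted score.

    For independent HWE SNPs, regressing the exposure on the raising
    allele count sum gives the variance-weighted mean of the per-allele
    effects: sum(beta_j * v_j) / sum(v_j) with v_j = 2 p_j (1 - p_j).
    """
    betas = np.asarray(betas, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    v = 2.0 * freqs * (1.0 - freqs)
    return float(np.sum(betas * v) / np.sum(v))


def calibrate_score_betas(target: float, base_betas, freqs) -> np.ndarray:
    """Rescale per-allele effects so the analytic unweighted-score
    coefficient equals ``target`` while preserving their ratios."""
    base = np.asarray(base_betas, dtype=float)
    current = unweighted_score_coefficient(base, freqs)
    if current == 0:
        raise InvalidParameterError("base betas give a zero score coefficient")
    return base * (target / current)
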