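"""Causal estimators for the Mendelian-randomisation stage.

Three estimators: the Wald-type ratio (gene-outcome log hazard ratio
over gene-exposure coefficient, exponentiated) for survival outcomes,
two-stage least squares for continuous outcomes, and MR-Egger weighted
regression as the pleiotropy sensitivity analysis.  Estimates are
expressed per 25 nmol/L genetically higher 25(OH)D by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import (
    InsufficientInstrumentsError,
    InvalidParameterError,
    SingularDesignError,
    UndefinedRatioError,
)
from .genetic_instruments import WEAK_INSTRUMENT_F

__all__ = [
    "GeneExposureEstimate",
    "GeneOutcomeEstimate",
    "WaldRatioEstimate",
    "TwoStageEstimate",
    "EggerResult",
    "wald_ratio",
    "two_stage_ls",
    "egger_regression",
    "snp_level_mr",
]


@dataclass
class GeneExposureEstimate:
    beta_gx: float  # nmol/L per score allele
    se_gx: float
    n: int = 0

    def __post_init__(self):
        if self.se_gx <= 0:
            raise InvalidParameterError("se_gx must be positive")


@dataclass
class GeneOutcomeEstimate:
    beta_gy: float  # log HR (or outcome units) per score allele
    se_gy: float
    outcome: str = ""

    def __post_init__(self):
        if self.se_gy <= 0:
            raise InvalidParameterError("se_gy must be positive")


@dataclass
class WaldRatioEstimate:
    log_hr_per_25: float
    se: float
    hr: float
    ci95: tuple[float, float]
    beta_gx: float
    beta_gy: float
    weak_instrument: bool = False


@dataclass
class TwoStageEstimate:
    beta_per_25: float
    se: float
    ci95: tuple[float, float]
    first_stage_f: float = float("nan")


@dataclass
class EggerResult:
    slope: float  # causal estimate per nmol/L of exposure
    slope_se: float
    intercept: float  # average directional pleiotropy
    intercept_se: float
    intercept_p: float
    n_snps: int


def wald_ratio(
    gene_outcome: GeneOutcomeEstimate,
    gene_exposure: GeneExposureEstimate,
    scale: float = 25.0,
    first_stage_f: float | None = None,
) -> WaldRatioEstimate:
    """Ratio estimator with a first-order delta-method standard error.

    log HR per `scale` nmol/L = scale * beta_gy / beta_gx;
    se = scale * sqrt(se_gy^2/beta_gx^2 + beta_gy^2 se_gx^2 / beta_gx^4).
    The 95% CI is the symmetric normal interval on the log scale,
    exponentiated.  A weak-instrument flag is attached when the supplied
    first-stage F is <= 10.
    """
    bx, by = gene_exposure.beta_gx, gene_outcome.beta_gy
    if bx == 0:
        raise UndefinedRatioError("gene-exposure coefficient is zero")
    est = scale * by / bx
    se = scale * np.sqrt(
        gene_outcome.se_gy**2 / bx**2 + by**2 * gene_exposure.se_gx**2 / bx**4
    )
    lo, hi = est - 1.96 * se, est + 1.96 * se
    weak = first_stage_f is not None and first_stage_f <= WEAK_INSTRUMENT_F
    return WaldRatioEstimate(
        log_hr_per_25=float(est),
        se=float(se),
        hr=float(np.exp(est)),
        ci95=(float(np.exp(lo)), float(np.exp(hi))),
        beta_gx=float(bx),
        beta_gy=float(by),
        weak_instrument=bool(weak),
    )


def _design(*blocks) -> np.ndarray:
    cols = [np.ones((len(blocks[0]), 1))]
    for b in blocks[1:]:
        if b is None:
            continue
        arr = np.asarray(b, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        cols.append(arr)
    return np.hstack(cols)


def two_stage_ls(
    instruments,
    exposure,
    outcome,
    covariates: pd.DataFrame | None = None,
    scale: float = 25.0,
) -> TwoStageEstimate:
    """Two-stage least squares with the proper 2SLS standard error.

    Stage 1 regresses the exposure on the instrument(s) plus covariates;
    stage 2 regresses the outcome on the fitted exposure plus the same
    covariates.  The residual variance for the SE uses the *observed*
    exposure (the 2SLS sandwich), not the naive stage-2 residuals, and
    the coefficient is rescaled per ``scale`` nmol/L.
    """
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    Z = np.asarray(instruments, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if not (len(x) == len(y) == len(Z)):
        raise InvalidParameterError("instruments, exposure and outcome must be aligned")
    C = None if covariates is None else np.asarray(covariates, dtype=float)

    Zfull = _design(x, C, Z)
    if np.linalg.matrix_rank(Zfull) < Zfull.shape[1]:
        raise SingularDesignError("first-stage design is rank deficient")
    coef1, *_ = np.linalg.lstsq(Zfull, x, rcond=None)
    xhat = Zfull @ coef1
    # first-stage F for the instrument block (joint Wald)
    resid1 = x - xhat
    df1 = len(x) - Zfull.shape[1]
    sigma1 = resid1 @ resid1 / df1
    ZtZinv = np.linalg.inv(Zfull.T @ Zfull)
    k = Z.shape[1]
    bz = coef1[-k:]
    Vz = sigma1 * ZtZinv[-k:, -k:]
    fstat = float(bz @ np.linalg.solve(Vz, bz) / k)
    if np.allclose(xhat, xhat[0]):
        raise UndefinedRatioError("instrument does not predict the exposure")

    W = _design(x, C, xhat)
    if np.linalg.matrix_rank(W) < W.shape[1]:
        raise SingularDesignError("second-stage design is rank deficient")
    coef2, *_ = np.linalg.lstsq(W, y, rcond=None)
    # 2SLS residuals evaluated at the observed exposure
    W_obs = _design(x, C, x)
    resid = y - W_obs @ coef2
    df = len(y) - W.shape[1]
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(W.T @ W)
    b = float(coef2[-1]) * scale
    se = float(np.sqrt(cov[-1, -1])) * scale
    return TwoStageEstimate(
        beta_per_25=b, se=se, ci95=(b - 1.96 * se, b + 1.96 * se),
        first_stage_f=fstat,
    )


def egger_regression(per_snp: pd.DataFrame) -> EggerResult:
    """MR-Egger: weighted regression of gene-outcome on gene-exposure
    effects with a free intercept.

    Weights are inverse outcome variances (1/se_gy^2); the intercept is
    the average directional pleiotropy, tested against t with
    n_snps - 2 df.  Requires >= 3 SNPs (a two-SNP score cannot be
    Egger-tested).
    """
    req = {"beta_gx", "beta_gy", "se_gy"}
    if not req.issubset(per_snp.columns):
        raise InvalidParameterError(f"per-SNP table needs columns {sorted(req)}")
    k = len(per_snp)
    if k < 3:
        raise InsufficientInstrumentsError(
            f"MR-Egger needs >= 3 instruments, got {k}"
        )
    if (per_snp["se_gy"] <= 0).any():
        raise InvalidParameterError("all se_gy must be positive")
    X = sm.add_constant(per_snp["beta_gx"].to_numpy())
    res = sm.WLS(
        per_snp["beta_gy"].to_numpy(), X, weights=1.0 / per_snp["se_gy"] ** 2
    ).fit()
    intercept, slope = res.params
    se_int, se_slope = res.bse
    t_int = intercept / se_int if se_int > 0 else np.inf
    p_int = float(2 * stats.t.sf(abs(t_int), df=k - 2))
    return EggerResult(
        slope=float(slope),
        slope_se=float(se_slope),
        intercept=float(intercept),
        intercept_se=float(se_int),
        intercept_p=p_int,
        n_snps=k,
    )


def snp_level_mr(
    per_snp: list[tuple[str, GeneExposureEstimate, GeneOutcomeEstimate]],
    scale: float = 25.0,
) -> pd.DataFrame:
    """Wald ratio per SNP; feeds MR-Egger and heterogeneity comparisons."""
    rows = []
    for snp_id, gx, gy in per_snp:
        w = wald_ratio(gy, gx, scale=scale)
        rows.append(
            {
                "snp_id": snp_id,
                "log_hr_per_25": w.log_hr_per_25,
                "se": w.se,
                "hr": w.hr,
                "ci_low": w.ci95[0],
                "ci_high": w.ci95[1],
                "beta_gx": w.beta_gx,
                "beta_gy": w.beta_gy,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "snp_id", "log_hr_per_25", "se", "hr", "ci_low", "ci_high",
            "beta_gx", "beta_gy",
        ],
    )
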