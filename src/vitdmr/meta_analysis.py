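"""Fixed- and random-effects pooling of per-cohort estimates.

Heterogeneity is summarised by Cochran's Q and I^2 = max(0, (Q-df)/Q);
pooling uses the inverse-variance fixed-effect model unless I^2 > 0.25,
in which case the DerSimonian-Laird random-effects model is selected.
Hazard ratios should be pooled on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError

__all__ = ["MetaResult", "heterogeneity", "pool"]

I2_RANDOM_EFFECTS_THRESHOLD = 0.25


@dataclass
class MetaResult:
    estimate: float
    se: float
    ci95: tuple[float, float]
    q: float
    df: int
    i2: float
    tau2: float
    model: str  # "fixed" or "random"
    weights: np.ndarray  # normalised to sum to 1, in input order


def _validate(estimates, ses):
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if est.shape != se.shape or est.ndim != 1:
        raise InvalidParameterError("estimates and ses must be 1-d and aligned")
    if len(est) < 2:
        raise InvalidParameterError("meta-analysis requires >= 2 studies")
    if np.any(se <= 0):
        raise InvalidParameterError("all standard errors must be positive")
    return est, se


def heterogeneity(estimates, ses) -> dict:
    """Cochran's Q (df = k-1) and I^2 around the fixed-effect mean."""
    est, se = _validate(estimates, ses)
    w = 1.0 / se**2
    theta_fixed = np.sum(w * est) / np.sum(w)
    q = float(np.sum(w * (est - theta_fixed) ** 2))
    df = len(est) - 1
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return {"Q": q, "df": df, "i2": i2}


def pool(estimates, ses, i2_threshold: float = I2_RANDOM_EFFECTS_THRESHOLD) -> MetaResult:
    """Inverse-variance pooling with the I^2-gated model choice.

    Random effects use the DerSimonian-Laird moment estimator
    tau^2 = max(0, (Q - df) / (sum w - sum w^2 / sum w)).
    """
    est, se = _validate(estimates, ses)
    het = heterogeneity(est, se)
    w = 1.0 / se**2
    if het["i2"] > i2_threshold:
        model = "random"
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (het["Q"] - het["df"]) / denom) if denom > 0 else 0.0
        w_star = 1.0 / (se**2 + tau2)
    else:
        model = "fixed"
        tau2 = 0.0
        w_star = w
    pooled = float(np.sum(w_star * est) / np.sum(w_star))
    pooled_se = float(np.sqrt(1.0 / np.sum(w_star)))
    return MetaResult(
        estimate=pooled,
        se=pooled_se,
        ci95=(pooled - 1.96 * pooled_se, pooled + 1.96 * pooled_se),
        q=het["Q"],
        df=het["df"],
        i2=het["i2"],
        tau2=float(tau2),
        model=model,
        weights=w_star / np.sum(w_star),
    )


def forest_table(labels, estimates, ses, result: MetaResult) -> pd.DataFrame:
    """Forest-plot-ready table: per-study rows plus the pooled summary."""
    rows = []
    for lab, e, s, w in zip(labels, estimates, ses, result.weights):
        rows.append(
            {
                "study": lab,
                "estimate": e,
                "ci_low": e - 1.96 * s,
                "ci_high": e + 1.96 * s,
                "weight": w,
            }
        )
    rows.append(
        {
            "study": f"pooled ({result.model})",
            "estimate": result.estimate,
            "ci_low": result.ci95[0],
            "ci_high": result.ci95[1],
            "weight": 1.0,
        }
    )
    return pd.DataFrame(rows)
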