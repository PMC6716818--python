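"""Allele-score construction and instrument-validity diagnostics.

A genetic score sums raising-allele dosages (optionally weighted); the
diagnostics mirror the standard Mendelian-randomisation checklist:
first-stage F-statistic (weak below 10), per-SNP Hardy-Weinberg
chi-square, and a confounder-balance table of per-allele regressions of
each measured covariate on dosage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidParameterError
from .regression_core import LinearFit, fit_ols

__all__ = [
    "AlleleScore",
    "InstrumentStrength",
    "build_allele_score",
    "hwe_test",
    "instrument_strength",
    "confounder_balance",
]

WEAK_INSTRUMENT_F = 10.0


@dataclass
class AlleleScore:
    values: pd.Series
    snp_ids: list[str]
    weights: np.ndarray


@dataclass
class InstrumentStrength:
    f_statistic: float
    weak: bool


def build_allele_score(
    dosages: pd.DataFrame, snp_ids: list[str], weights=None
) -> AlleleScore:
    """Sum of raising-allele dosages over the requested SNPs.

    Default weights are all 1 (the unweighted score used as the main
    instrument); weights must be nonnegative.
    """
    missing = [s for s in snp_ids if s not in dosages.columns]
    if missing:
        raise InvalidParameterError(f"unknown SNP id(s): {missing}")
    if weights is None:
        weights = np.ones(len(snp_ids))
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(snp_ids):
        raise InvalidParameterError("one weight per SNP required")
    if np.any(weights < 0):
        raise InvalidParameterError("negative score weights are not allowed")
    vals = dosages[snp_ids].to_numpy(dtype=float) @ weights
    return AlleleScore(
        values=pd.Series(vals, index=dosages.index, name="score"),
        snp_ids=list(snp_ids),
        weights=weights,
    )


def hwe_test(counts) -> tuple[float, float]:
    """1-df chi-square against Hardy-Weinberg proportions.

    ``counts`` are genotype counts (n0, n1, n2) by raising-allele
    dosage; expectation uses the sample allele frequency.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (3,) or np.any(counts < 0):
        raise InvalidParameterError("counts must be three nonnegative genotype counts")
    n = counts.sum()
    if n == 0:
        raise InvalidParameterError("zero total genotype count")
    p = (counts[1] + 2 * counts[2]) / (2 * n)
    expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    if p in (0.0, 1.0):
        return 0.0, 1.0  # monomorphic: trivially consistent with HWE
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def instrument_strength(first_stage: LinearFit, term: str = "score") -> InstrumentStrength:
    """First-stage F for the score term, computed as the squared Wald t.

    F <= 10 is flagged weak; a zero SE with nonzero coefficient yields
    an infinite F rather than an error.
    """
    beta = first_stage.beta(term)
    se = first_stage.se(term)
    if se == 0:
        f = float("inf") if beta != 0 else 0.0
    else:
        f = (beta / se) ** 2
    return InstrumentStrength(f_statistic=float(f), weak=bool(f <= WEAK_INSTRUMENT_F))


def confounder_balance(dosage, covariates: pd.DataFrame) -> pd.DataFrame:
    """Per-allele association of each covariate with a dosage or score.

    Regresses covariate on dosage; under valid instruments every row
    should be null.  Constant covariates are skipped with a warning.
    """
    g = np.asarray(dosage, dtype=float)
    rows = []
    for name in covariates.columns:
        y = covariates[name].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            warnings.warn(f"covariate {name!r} is constant; skipped", stacklevel=2)
            continue
        fit = fit_ols(y, pd.DataFrame({"dosage": g}))
        rows.append(
            {
                "covariate": name,
                "beta": fit.beta("dosage"),
                "se": fit.se("dosage"),
                "p": fit.p("dosage"),
            }
        )
    return pd.DataFrame(rows, columns=["covariate", "beta", "se", "p"])
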