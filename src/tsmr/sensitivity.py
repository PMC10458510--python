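"""Heterogeneity, pleiotropy, directionality and multiple-testing checks.

* Cochran's Q measures heterogeneity of the per-SNP causal estimates around
  a fitted effect; under homogeneity it is chi-square with nSNP-1 df (IVW)
  or nSNP-2 df (around the Egger fit with its free intercept).  A Q-test
  p below 0.05 flags heterogeneity.
* The MR-Egger intercept tests directional horizontal pleiotropy (t, n-2 df).
* The Steiger directionality test compares instrument-explained variance in
  exposure vs outcome: causal direction exposure->outcome is supported when
  the instruments explain more variance in the exposure.  The comparison
  p-value uses Fisher's z transform of the two multiple correlations.
* Bonferroni correction divides alpha by the number of tests in a category
  (taxonomic rank, metabolite panel, pathway panel).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .estimators import EggerResult, InsufficientInstrumentsError, _egger_design
from .gwas_io import HarmonizedInstrumentSet

_MIN_P = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class CorrectionScheme:
    """Bonferroni scheme for one exposure category."""

    category: str
    divisor: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.divisor < 1:
            raise ValueError("divisor must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0,1)")

    @property
    def threshold(self) -> float:
        return self.alpha / self.divisor


#: default divisors: counts of initially significant exposures per category
DEFAULT_SCHEMES: dict[str, CorrectionScheme] = {
    "order": CorrectionScheme("order", 1),
    "family": CorrectionScheme("family", 3),
    "genus": CorrectionScheme("genus", 15),
    "metabolite": CorrectionScheme("metabolite", 9),
    "pathway": CorrectionScheme("pathway", 20),
}


@dataclass(frozen=True)
class QResult:
    q: float
    df: int
    p: float


@dataclass(frozen=True)
class SteigerResult:
    direction: bool
    p: float
    r2_exposure: float
    r2_outcome: float


@dataclass(frozen=True)
class SensitivityReport:
    """All sensitivity columns for one exposure-outcome pair."""

    q_ivw: QResult | None
    q_egger: QResult | None
    egger_intercept: float | None
    egger_intercept_se: float | None
    egger_intercept_p: float | None
    steiger_direction: bool
    steiger_p: float
    bonferroni_threshold: float
    passes_correction: bool


def chi_square_upper_tail(q: float, df: int) -> float:
    """Upper-tail chi-square probability P(X >= q) with ``df`` degrees of freedom."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(min(max(stats.chi2.sf(q, df), _MIN_P), 1.0))


def cochran_q(instruments: HarmonizedInstrumentSet, fitted_b: float,
              df_loss: int = 1, intercept: float = 0.0) -> QResult:
    """Cochran's Q around a fitted causal effect.

    ``Q = sum_j (by_j - intercept - b*bx_j)^2 / sy_j^2`` — identical to the
    first-order ratio-space form ``sum w_j (ratio_j - b)^2`` with
    ``w_j = bx_j^2/sy_j^2`` when the intercept is zero.  ``df_loss`` is 1
    for the IVW fit and 2 for the Egger fit (whose residuals are taken
    about the intercept model, in the bx >= 0 orientation).
    """
    n = len(instruments)
    df = n - df_loss
    if df < 1:
        raise InsufficientInstrumentsError(
            f"Cochran's Q needs > {df_loss} instruments, got {n}")
    if df_loss >= 2 or intercept != 0.0:
        x, y, sy = _egger_design(instruments)
    else:
        x = instruments.beta_exposure
        y = instruments.beta_outcome
        sy = instruments.se_outcome
    resid = y - intercept - fitted_b * x
    q = float(np.sum((resid / sy) ** 2))
    return QResult(q, df, chi_square_upper_tail(q, df))


def cochran_q_egger(instruments: HarmonizedInstrumentSet,
                    egger: EggerResult) -> QResult:
    """Q around the Egger fit (df = nSNP - 2)."""
    return cochran_q(instruments, egger.slope.b, df_loss=2,
                     intercept=egger.intercept)


def egger_intercept_test(egger: EggerResult) -> tuple[float, float, float]:
    """``(intercept, se, p)`` — directional pleiotropy flagged when p < 0.05."""
    return egger.intercept, egger.intercept_se, egger.intercept_p


def steiger_test(instruments: HarmonizedInstrumentSet,
                 n_exposure: float | None = None,
                 n_outcome: float | None = None,
                 outcome_type: str = "binary") -> SteigerResult:
    """MR Steiger directionality test.

    Instrument-explained variance in the exposure uses the frequency
    formula ``sum 2p(1-p)bx^2``; in the outcome it is summed per-SNP
    squared correlations recovered from z-statistics, ``r = z/sqrt(z^2+N)``
    (binary outcomes on the observed scale).  Direction is TRUE — no
    reverse causation — when the exposure variance exceeds the outcome
    variance; the p-value compares the Fisher-z-transformed multiple
    correlations between the two (independent) samples.
    """
    if len(instruments) == 0:
        raise InsufficientInstrumentsError("steiger_test needs >= 1 instrument")
    if outcome_type not in ("binary", "continuous"):
        raise ValueError("outcome_type must be 'binary' or 'continuous'")
    n_exp = instruments.n_exposure if n_exposure is None else n_exposure
    n_out = instruments.n_outcome if n_outcome is None else n_outcome
    if not (n_exp > 3 and n_out > 3):
        raise ValueError("sample sizes must be known and > 3")

    eaf = instruments.eaf_exposure
    if np.any(~np.isfinite(eaf)):
        raise ValueError("steiger_test requires exposure EAFs")
    bx = instruments.beta_exposure
    r2_exp = float(np.sum(2.0 * eaf * (1.0 - eaf) * bx ** 2))

    z = instruments.beta_outcome / instruments.se_outcome
    r_out = z / np.sqrt(z ** 2 + n_out)
    r2_out = float(np.sum(r_out ** 2))

    r_exp_tot = math.sqrt(min(r2_exp, 1.0 - 1e-12))
    r_out_tot = math.sqrt(min(r2_out, 1.0 - 1e-12))
    zdiff = ((math.atanh(r_exp_tot) - math.atanh(r_out_tot))
             / math.sqrt(1.0 / (n_exp - 3.0) + 1.0 / (n_out - 3.0)))
    p = float(min(max(2.0 * stats.norm.sf(abs(zdiff)), _MIN_P), 1.0))
    return SteigerResult(r2_exp > r2_out, p, r2_exp, r2_out)


def bonferroni(pvalues: Mapping[str, float],
               scheme: CorrectionScheme) -> dict[str, tuple[float, bool]]:
    """Apply a category's Bonferroni threshold: passes iff p < alpha/divisor (strict)."""
    thr = scheme.threshold
    return {label: (thr, p < thr) for label, p in pvalues.items()}


def sensitivity_report(instruments: HarmonizedInstrumentSet,
                       ivw_b: float,
                       egger: EggerResult | None,
                       scheme: CorrectionScheme,
                       ivw_p: float,
                       outcome_type: str = "binary") -> SensitivityReport:
    """Assemble the full sensitivity panel for one exposure-outcome pair."""
    q_ivw = (cochran_q(instruments, ivw_b, df_loss=1)
             if len(instruments) >= 2 else None)
    if egger is not None:
        q_egger = cochran_q_egger(instruments, egger)
        icpt, icpt_se, icpt_p = egger_intercept_test(egger)
    else:
        q_egger = icpt = icpt_se = icpt_p = None
    steiger = steiger_test(instruments, outcome_type=outcome_type)
    thr = scheme.threshold
    return SensitivityReport(
        q_ivw=q_ivw, q_egger=q_egger,
        egger_intercept=icpt, egger_intercept_se=icpt_se,
        egger_intercept_p=icpt_p,
        steiger_direction=steiger.direction, steiger_p=steiger.p,
        bonferroni_threshold=thr, passes_correction=ivw_p < thr)
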