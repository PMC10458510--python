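"""Causal-effect estimators for two-sample MR.

Five estimators are provided, all operating on a harmonized instrument set
with per-SNP exposure effects ``bx_j`` (SE ``sx_j``) and outcome effects
``by_j`` (SE ``sy_j``):

* Wald ratio (single SNP): ``by/bx`` with first-order SE ``sy/|bx|``.
* IVW: fixed-effect inverse-variance-weighted combination of Wald ratios,
  ``b = sum(bx*by/sy^2) / sum(bx^2/sy^2)``; the main analysis method.
* MR-Egger: weighted regression of ``by`` on ``bx`` with a free intercept;
  a nonzero intercept indicates directional horizontal pleiotropy and the
  slope is a pleiotropy-robust estimate under the InSIDE assumption.
* Weighted median: weighted 50% quantile of the per-SNP ratios, consistent
  when valid instruments carry more than half the weight.
* Simple / weighted mode: location of the maximum of a Gaussian kernel
  density over the per-SNP ratios, consistent when the largest group of
  instruments shares the true effect (ZEMPA).

Bootstrap standard errors for the median and mode estimators resample
``bx_j`` and ``by_j`` from normal distributions with their reported SEs.
p-value conventions follow the reference two-sample-MR implementations:
normal for IVW, weighted median and Wald ratio; Student t with n-2 df for
Egger slope and intercept; t with n-1 df for the mode estimators.

Effects are on the log-odds scale for binary outcomes; ``to_odds_ratio``
maps an estimate to OR with a normal-theory confidence interval.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .gwas_io import HarmonizedInstrumentSet

_MIN_P = float(np.finfo(float).tiny)


class InsufficientInstrumentsError(ValueError):
    """Too few instruments for the requested estimator."""


class DegenerateInstrumentError(ValueError):
    """An instrument violates an estimator precondition (e.g. bx = 0)."""


def _norm_p(z: float) -> float:
    return float(min(max(2.0 * stats.norm.sf(abs(z)), _MIN_P), 1.0))


def _t_p(t: float, df: int) -> float:
    return float(min(max(2.0 * stats.t.sf(abs(t), df), _MIN_P), 1.0))


def to_odds_ratio(b: float, se: float, level: float = 0.95):
    """Map a log-odds effect to ``(OR, CI low, CI high)`` at the given level."""
    if se < 0:
        raise ValueError("se must be >= 0")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0,1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    # np.exp saturates to inf/0 instead of raising on extreme log-odds
    with np.errstate(over="ignore"):
        return (float(np.exp(b)), float(np.exp(b - z * se)),
                float(np.exp(b + z * se)))


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate in Table-style form."""

    method: str
    b: float
    se: float
    pvalue: float
    n_snp: int
    or_: float
    ci_low: float
    ci_high: float

    @classmethod
    def build(cls, method: str, b: float, se: float, pvalue: float,
              n_snp: int) -> "MREstimate":
        or_, lo, hi = to_odds_ratio(b, se)
        return cls(method, float(b), float(se), float(pvalue), n_snp, or_, lo, hi)


@dataclass(frozen=True)
class RatioEstimates:
    """Per-SNP Wald ratios, their first-order SEs, and IV weights."""

    ratios: np.ndarray
    ses: np.ndarray
    weights: np.ndarray  # bx^2 / sy^2 == 1 / ses^2


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger slope plus the pleiotropy intercept."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_p: float
    sigma: float  # residual scale of the weighted fit (floored at 1 for SEs)
    n_snp: int


def ratio_estimates(instruments: HarmonizedInstrumentSet) -> RatioEstimates:
    """Per-SNP Wald ratios with inverse-variance weights."""
    bx = instruments.beta_exposure
    by = instruments.beta_outcome
    sy = instruments.se_outcome
    if np.any(bx == 0):
        raise DegenerateInstrumentError("instrument with beta_exposure = 0")
    ratios = by / bx
    ses = sy / np.abs(bx)
    weights = 1.0 / ses ** 2
    if not np.all(np.isfinite(weights)) or np.any(weights <= 0):
        raise DegenerateInstrumentError("nonpositive or nonfinite ratio weight")
    return RatioEstimates(ratios, ses, weights)


def wald_ratio(instruments: HarmonizedInstrumentSet) -> MREstimate:
    """Single-SNP causal estimate ``by/bx`` with SE ``sy/|bx|``."""
    if len(instruments) != 1:
        raise InsufficientInstrumentsError("wald_ratio needs exactly 1 instrument")
    r = ratio_estimates(instruments)
    b, se = float(r.ratios[0]), float(r.ses[0])
    return MREstimate.build("Wald ratio", b, se, _norm_p(b / se), 1)


def ivw(instruments: HarmonizedInstrumentSet,
        random_effects: bool = False) -> MREstimate:
    """Fixed-effect inverse-variance-weighted estimate.

    ``random_effects=True`` switches to a multiplicative random-effects
    model (residual scale applied to the SE, floored at 1).
    """
    if len(instruments) < 2:
        logging.getLogger(__name__).warning(
            "ivw called with %d instrument(s); falling back to Wald ratio",
            len(instruments))
        return wald_ratio(instruments)
    bx = instruments.beta_exposure
    by = instruments.beta_outcome
    sy = instruments.se_outcome
    w = bx ** 2 / sy ** 2
    denom = float(np.sum(w))
    b = float(np.sum(bx * by / sy ** 2)) / denom
    se = math.sqrt(1.0 / denom)
    if random_effects:
        r = ratio_estimates(instruments)
        q = float(np.sum(r.weights * (r.ratios - b) ** 2))
        sigma2 = q / (len(instruments) - 1)
        se *= math.sqrt(max(sigma2, 1.0))
    return MREstimate.build("IVW", b, se, _norm_p(b / se), len(instruments))


def _egger_design(instruments: HarmonizedInstrumentSet):
    """Orient pairs so beta_exposure >= 0 (the Egger sign convention)."""
    bx = instruments.beta_exposure
    by = instruments.beta_outcome
    sy = instruments.se_outcome
    sign = np.where(bx < 0, -1.0, 1.0)
    return bx * sign, by * sign, sy


def mr_egger(instruments: HarmonizedInstrumentSet) -> EggerResult:
    """MR-Egger weighted regression with a free pleiotropy intercept.

    Weighted least squares of ``by`` on ``bx`` (weights ``1/sy^2``) after
    orienting all pairs to ``bx >= 0``.  SEs are inflated by the residual
    scale, floored at 1; p-values use t(n-2).
    """
    n = len(instruments)
    if n < 3:
        raise InsufficientInstrumentsError(
            f"mr_egger needs >= 3 instruments, got {n}")
    x, y, sy = _egger_design(instruments)
    w = 1.0 / sy ** 2
    # weighted normal equations for [intercept, slope]
    design = np.column_stack([np.ones(n), x])
    xtwx = design.T @ (design * w[:, None])
    xtwy = design.T @ (w * y)
    try:
        cov_unit = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError as exc:
        raise DegenerateInstrumentError("singular Egger design") from exc
    coef = cov_unit @ xtwy
    resid = y - design @ coef
    sigma = math.sqrt(float(np.sum(w * resid ** 2)) / (n - 2))
    infl = max(sigma, 1.0)
    se = np.sqrt(np.diag(cov_unit)) * infl
    slope_p = _t_p(coef[1] / se[1], n - 2)
    intercept_p = _t_p(coef[0] / se[0], n - 2)
    slope = MREstimate.build("MR Egger", float(coef[1]), float(se[1]),
                             slope_p, n)
    return EggerResult(slope, float(coef[0]), float(se[0]), intercept_p,
                       sigma, n)


# ---------------------------------------------------------------------------
# Median and mode point estimators (shared by the bootstrap machinery)
# ---------------------------------------------------------------------------

def weighted_median_estimate(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted 50% quantile with the standard piecewise-linear interpolation.

    Ratios are sorted; the cumulative weight minus half of each SNP's own
    weight (normalized to total 1) defines the empirical quantile function,
    which is linearly interpolated at 0.5.  Exactly tied ratios are merged
    (weights summed) first, which makes the estimate independent of tie
    ordering and exactly sign-equivariant.
    """
    r_in = np.asarray(ratios, dtype=float)
    w_in = np.asarray(weights, dtype=float)
    if np.any(w_in <= 0) or not np.all(np.isfinite(w_in)):
        raise DegenerateInstrumentError("weighted median requires positive weights")
    r, inverse = np.unique(r_in, return_inverse=True)
    w = np.bincount(inverse, weights=w_in)
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, cum, r))


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    n = len(ratios)
    sd = float(np.std(ratios, ddof=1))
    mad = float(stats.median_abs_deviation(ratios, scale="normal"))
    scale = min(sd, mad)
    if scale == 0.0:
        scale = sd  # MAD collapses when >half the ratios tie; sd still informative
    return phi * 0.9 * scale * n ** (-1.0 / 5.0)


def kernel_mode_estimate(ratios: np.ndarray, weights: np.ndarray,
                         phi: float = 1.0) -> float:
    """Argmax of the weighted Gaussian kernel density of the ratios.

    Bandwidth is ``phi * 0.9 * min(sd, mad/0.6745) * n^(-1/5)``.  A coarse
    grid locates the global peak; a bounded scalar optimization refines it.
    All-identical ratios return the common value directly.
    """
    r = np.asarray(ratios, dtype=float)
    w = np.asarray(weights, dtype=float)
    w = w / np.sum(w)
    h = _mode_bandwidth(r, phi)
    if h == 0.0:
        return float(r[0])

    def neg_density(x):
        with np.errstate(over="ignore"):
            return -np.sum(w * np.exp(-0.5 * ((x - r) / h) ** 2))

    # candidate peaks: a coarse grid plus the ratio locations themselves
    # (peaks can fall between grid points when the bandwidth is narrow)
    grid = np.concatenate([np.linspace(r.min() - 3 * h, r.max() + 3 * h, 2048), r])
    with np.errstate(over="ignore"):
        dens = (w[:, None]
                * np.exp(-0.5 * ((grid[None, :] - r[:, None]) / h) ** 2)).sum(axis=0)
    x0 = float(grid[int(np.argmax(dens))])
    res = optimize.minimize_scalar(neg_density, bounds=(x0 - h, x0 + h),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    return float(res.x) if -res.fun >= -neg_density(x0) else x0


def _parametric_bootstrap_se(instruments: HarmonizedInstrumentSet,
                             point, n_boot: int, seed: int) -> float:
    """SE of a ratio-based point estimator under parametric resampling.

    Each replicate redraws every ``bx_j`` and ``by_j`` from normals centred
    on the observed effects with their reported SEs, recomputes ratios and
    inverse-variance weights, and re-evaluates ``point(ratios, weights)``.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    bx = instruments.beta_exposure
    sx = instruments.se_exposure
    by = instruments.beta_outcome
    sy = instruments.se_outcome
    j = bx.size
    est = np.empty(n_boot)
    for k in range(n_boot):
        bxs = bx + sx * rng.standard_normal(j)
        bys = by + sy * rng.standard_normal(j)
        bxs = np.where(bxs == 0.0, np.finfo(float).eps, bxs)
        est[k] = point(bys / bxs, bxs ** 2 / sy ** 2)
    return float(np.std(est, ddof=1))


def weighted_median(instruments: HarmonizedInstrumentSet,
                    n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE."""
    n = len(instruments)
    if n < 3:
        raise InsufficientInstrumentsError(
            f"weighted_median needs >= 3 instruments, got {n}")
    r = ratio_estimates(instruments)
    b = weighted_median_estimate(r.ratios, r.weights)
    se = _parametric_bootstrap_se(instruments, weighted_median_estimate,
                                  n_boot, seed)
    p = _norm_p(b / se) if se > 0 else (1.0 if b == 0 else _MIN_P)
    return MREstimate.build("Weighted median", b, se, p, n)


def mode_estimate(instruments: HarmonizedInstrumentSet,
                  weighted: bool = False, phi: float = 1.0,
                  n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Simple (equal-weight) or weighted mode-based estimator.

    The weighted variant weights each ratio's kernel by its inverse-variance
    weight.  SE comes from the same parametric bootstrap as the weighted
    median; p-values use t(n-1).
    """
    n = len(instruments)
    if n < 3:
        raise InsufficientInstrumentsError(
            f"mode_estimate needs >= 3 instruments, got {n}")
    if phi <= 0:
        raise ValueError("phi must be positive")
    r = ratio_estimates(instruments)

    if weighted:
        def point(ratios, weights):
            return kernel_mode_estimate(ratios, weights, phi)
    else:
        def point(ratios, weights):
            return kernel_mode_estimate(ratios, np.ones_like(ratios), phi)

    b = point(r.ratios, r.weights)
    se = _parametric_bootstrap_se(instruments, point, n_boot, seed)
    p = _t_p(b / se, n - 1) if se > 0 else (1.0 if b == 0 else _MIN_P)
    label = "Weighted mode" if weighted else "Simple mode"
    return MREstimate.build(label, b, se, p, n)


def all_estimates(instruments: HarmonizedInstrumentSet,
                  n_boot: int = 1000, phi: float = 1.0,
                  seed: int = 0) -> list[MREstimate]:
    """Every estimator the instrument count permits, IVW first.

    1 instrument -> Wald ratio only; 2 -> IVW; >= 3 -> IVW, MR Egger,
    weighted median, simple mode, weighted mode.
    """
    n = len(instruments)
    if n == 1:
        return [wald_ratio(instruments)]
    out = [ivw(instruments)]
    if n >= 3:
        out.append(mr_egger(instruments).slope)
        out.append(weighted_median(instruments, n_boot=n_boot, seed=seed))
        out.append(mode_estimate(instruments, weighted=False, phi=phi,
                                 n_boot=n_boot, seed=seed + 1))
        out.append(mode_estimate(instruments, weighted=True, phi=phi,
                                 n_boot=n_boot, seed=seed + 2))
    return out
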