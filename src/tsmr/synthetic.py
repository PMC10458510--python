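"""Synthetic two-sample GWAS summary statistics.

Generates exposure and outcome association tables with the structure the
MR pipeline assumes — per-SNP effects, standard errors consistent with the
stated sample sizes and allele frequencies, a true causal effect, optional
horizontal pleiotropy, and below-threshold background SNPs — so the whole
analysis is testable without downloading any cohort data.

The generative model is summary-level: for instrument j,

    eaf_j  ~ Uniform(eaf_range)
    gamma_j ~ Normal(0, gamma_sd^2)            (|.| if positive_gamma)
    se_Xj  = 1 / sqrt(2 eaf_j (1-eaf_j) N_exp)
    bx_j   = gamma_j + Normal(0, se_Xj^2)
    alpha_j = pleiotropy_mean + Normal(0, pleiotropy_sd^2) [+ 0.5 gamma_j]
    se_Yj  = 1 / sqrt(2 eaf_j (1-eaf_j) N_out * cf (1-cf))   (binary outcome)
    by_j   = theta * gamma_j + alpha_j + Normal(0, se_Yj^2)

Null SNPs are drawn with gamma = 0; reverse scenarios swap the generative
roles of exposure and outcome.  The bracketed term correlates pleiotropy
with instrument strength, violating the InSIDE assumption.  No LD is
simulated between SNPs (the pipeline assumes post-clumping independence);
instrument positions are spaced > 10 Mb apart so distance-only clumping is
a no-op on them.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
from scipy import stats

from .gwas_io import SummaryStatRecord

_MIN_P = float(np.finfo(float).tiny)

# non-palindromic allele pairs, cycled deterministically over SNPs
_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"),
                 ("A", "C"), ("G", "T"))

_N_CHROM = 22
_SPACING = 25_000_000  # bp between same-chromosome SNPs (> 10,000 kb window)


@dataclass(frozen=True)
class SimulationScenario:
    """Generative parameters for one synthetic exposure-outcome pair."""

    n_instruments: int = 100
    n_null_snps: int = 0
    theta: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    inside_violation: bool = False
    gamma_sd: float = 0.1
    positive_gamma: bool = False
    n_exposure: float = 18_340.0
    n_outcome: float = 218_792.0
    case_fraction: float | None = 35_847.0 / 218_792.0
    eaf_range: tuple[float, float] = (0.1, 0.9)
    reverse: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_instruments < 1:
            raise ValueError("n_instruments must be >= 1")
        if self.n_null_snps < 0:
            raise ValueError("n_null_snps must be >= 0")
        if self.gamma_sd < 0 or self.pleiotropy_sd < 0:
            raise ValueError("sd parameters must be >= 0")
        lo, hi = self.eaf_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("eaf_range must be inside (0,1)")
        if self.n_exposure <= 0 or self.n_outcome <= 0:
            raise ValueError("sample sizes must be positive")
        if self.case_fraction is not None and not (0.0 < self.case_fraction < 1.0):
            raise ValueError("case_fraction must be in (0,1) or None")


def _se_continuous(eaf: np.ndarray, n: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)


def _se_binary(eaf: np.ndarray, n: float, case_fraction: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n
                         * case_fraction * (1.0 - case_fraction))


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, _MIN_P, 1.0)


def _records(snp_ids, chrom, pos, alleles, eaf, beta, se, pval, n
             ) -> list[SummaryStatRecord]:
    return [
        SummaryStatRecord(
            snp_id=snp_ids[j], chrom=str(chrom[j]), pos=int(pos[j]),
            effect_allele=alleles[j][0], other_allele=alleles[j][1],
            eaf=float(eaf[j]), beta=float(beta[j]), se=float(se[j]),
            pvalue=float(pval[j]), n=float(n))
        for j in range(len(snp_ids))
    ]


def simulate_effects(scenario: SimulationScenario) -> dict[str, np.ndarray]:
    """Draw the effect-size arrays for one synthetic pair.

    Returns arrays over the ``n_instruments + n_null_snps`` SNPs:
    ``eaf, bx, se_x, by, se_y`` plus the instrument-level truth
    ``gamma, alpha``.  Deterministic under ``scenario.seed``: the global
    seed expands into per-component substreams (frequencies, instrument
    effects, exposure noise, pleiotropy, outcome noise, null block), so
    changing e.g. the number of null SNPs never shifts the instruments'
    draws.  This is the fast path used by replicate studies;
    :func:`simulate_pair` wraps it into validated summary-stat records.
    """
    sc = scenario
    ss = np.random.SeedSequence(sc.seed)
    rng_eaf, rng_gamma, rng_x, rng_pleio, rng_y, rng_null = (
        np.random.default_rng(child) for child in ss.spawn(6))

    j = sc.n_instruments
    k = sc.n_null_snps
    eaf = rng_eaf.uniform(sc.eaf_range[0], sc.eaf_range[1], j + k)

    gamma = rng_gamma.normal(0.0, sc.gamma_sd, j)
    if sc.positive_gamma:
        gamma = np.abs(gamma)
    alpha = sc.pleiotropy_mean + rng_pleio.normal(0.0, sc.pleiotropy_sd, j)
    if sc.inside_violation:
        alpha = alpha + 0.5 * gamma

    se_x = _se_continuous(eaf, sc.n_exposure)
    if sc.case_fraction is None:
        se_y = _se_continuous(eaf, sc.n_outcome)
    else:
        se_y = _se_binary(eaf, sc.n_outcome, sc.case_fraction)

    noise_x = rng_x.standard_normal(j + k)
    noise_y = rng_y.standard_normal(j + k)
    # null-block stream kept distinct so instrument draws are invariant to k
    null_x = rng_null.standard_normal(k) if k else np.empty(0)

    if not sc.reverse:
        bx = np.concatenate([gamma + noise_x[:j] * se_x[:j],
                             null_x * se_x[j:]])
        by = np.concatenate([sc.theta * gamma + alpha + noise_y[:j] * se_y[:j],
                             noise_y[j:] * se_y[j:]])
    else:
        # SNPs act on the outcome first; exposure effects are downstream
        by = np.concatenate([gamma + noise_y[:j] * se_y[:j],
                             null_x * se_y[j:]])
        bx = np.concatenate([sc.theta * gamma + alpha + noise_x[:j] * se_x[:j],
                             noise_x[j:] * se_x[j:]])
    return {"eaf": eaf, "bx": bx, "se_x": se_x, "by": by, "se_y": se_y,
            "gamma": gamma, "alpha": alpha}


def simulate_pair(scenario: SimulationScenario
                  ) -> tuple[list[SummaryStatRecord],
                             list[SummaryStatRecord],
                             dict[str, Any]]:
    """Draw one synthetic (exposure, outcome, truth) triple as record lists."""
    sc = scenario
    eff = simulate_effects(sc)
    eaf, bx, se_x = eff["eaf"], eff["bx"], eff["se_x"]
    by, se_y = eff["by"], eff["se_y"]
    j, k = sc.n_instruments, sc.n_null_snps

    idx = np.arange(j + k)
    snp_ids = [f"rs{1_000_000 + int(i)}" for i in idx]
    chrom = (idx % _N_CHROM) + 1
    # instruments on a 25 Mb grid; nulls offset 12.5 Mb, outside any window
    pos = 1 + (idx // _N_CHROM) * _SPACING
    pos = np.where(idx < j, pos, pos + _SPACING // 2)
    alleles = [_ALLELE_PAIRS[int(i) % len(_ALLELE_PAIRS)] for i in idx]

    exposure = _records(snp_ids, chrom, pos, alleles, eaf, bx, se_x,
                        _two_sided_p(bx, se_x), sc.n_exposure)
    outcome = _records(snp_ids, chrom, pos, alleles, eaf, by, se_y,
                       _two_sided_p(by, se_y), sc.n_outcome)
    truth = {
        "theta": sc.theta,
        "gamma": eff["gamma"].tolist(),
        "alpha": eff["alpha"].tolist(),
        "instrument_ids": snp_ids[:j],
        "reverse": sc.reverse,
        "seed": sc.seed,
    }
    return exposure, outcome, truth


def scenario_presets(seed: int = 0) -> dict[str, SimulationScenario]:
    """Named scenarios covering the study's designs.

    Sample sizes echo the real cohorts: 18,340 for the microbiome exposure
    GWAS, 218,792 (35,847 cases) for the URTI outcome and 463,010 (3,135
    cases) for the LRTI outcome.
    """
    urti = dict(n_exposure=18_340.0, n_outcome=218_792.0,
                case_fraction=35_847.0 / 218_792.0)
    lrti = dict(n_exposure=18_340.0, n_outcome=463_010.0,
                case_fraction=3_135.0 / 463_010.0)
    base = dict(n_instruments=100, gamma_sd=0.1, seed=seed, **urti)
    return {
        "null": SimulationScenario(theta=0.0, n_null_snps=1000, **base),
        "causal": SimulationScenario(theta=0.1, **base),
        "causal_rare_outcome": SimulationScenario(
            theta=0.1, n_instruments=100, gamma_sd=0.1, seed=seed, **lrti),
        "directional_pleiotropy": SimulationScenario(
            theta=0.1, n_instruments=200, pleiotropy_mean=0.02,
            pleiotropy_sd=0.005, positive_gamma=True, gamma_sd=0.1,
            seed=seed, **urti),
        "heterogeneous": SimulationScenario(
            theta=0.1, pleiotropy_mean=0.0, pleiotropy_sd=0.02, **base),
        "reverse": SimulationScenario(
            theta=0.2, reverse=True, n_instruments=100, gamma_sd=0.1,
            seed=seed, **urti),
        "weak_instruments": SimulationScenario(
            theta=0.1, n_instruments=100, gamma_sd=0.02, seed=seed, **urti),
    }
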