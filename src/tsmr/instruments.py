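"""Instrumental-variable selection for two-sample MR.

Selection follows the usual pipeline for microbiome / metabolite GWAS
exposures: a genome-wide suggestive significance cut (p < 1e-5, since
strictly genome-wide-significant hits are too few for these traits), a
minor-allele-frequency floor, greedy LD clumping so retained instruments
are approximately independent, removal of SNPs annotated to known
confounders, and a weak-instrument filter on the F statistic.

Explained variance per SNP uses

    R^2 = 2 * EAF * (1 - EAF) * beta^2                    (i < 10 instruments)
    R^2 = beta^2 / (beta^2 + N * SE^2)                    (i >= 10)

where the second form is the algebraic reduction of the frequency-weighted
ratio 2p(1-p)b^2 / (2p(1-p)b^2 + 2p(1-p)N se^2).  Instrument strength is

    F = [R^2 / (1 - R^2)] * [(N - 1 - i) / i]

with N the exposure sample size and i the number of instruments; sets or
single SNPs with F < 10 are conventionally considered weak.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .gwas_io import SummaryStatRecord

log = logging.getLogger(__name__)


class DegenerateInputError(ValueError):
    """Inputs outside the domain of a formula (eaf in {0,1}, n <= i+1, ...)."""


@dataclass(frozen=True)
class ClumpConfig:
    """Instrument-selection thresholds.

    Defaults are the conventional values for suggestive-threshold MR on
    microbial-abundance exposures: p < 1e-5, MAF >= 0.01, clumping at
    r^2 0.001 within a 10,000 kb window.
    """

    r2_threshold: float = 0.001
    window_kb: int = 10_000
    p_threshold: float = 1e-5
    maf_min: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 < self.r2_threshold < 1.0):
            raise ValueError("r2_threshold must be in (0,1)")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")
        if not (0.0 < self.p_threshold <= 1.0):
            raise ValueError("p_threshold must be in (0,1]")
        if not (0.0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must be in [0,0.5)")


@dataclass(frozen=True)
class InstrumentStrength:
    """Explained variance and F statistic for an instrument set."""

    r2_per_snp: tuple[float, ...]
    r2_total: float
    f_statistic: float
    n: float
    i: int

    def __post_init__(self) -> None:
        if self.i < 1:
            raise ValueError("i must be >= 1")
        if not (0.0 <= self.r2_total < 1.0):
            raise ValueError("r2_total must be in [0,1)")
        if self.f_statistic < 0:
            raise ValueError("f_statistic must be >= 0")


def threshold_filter(
    records: Sequence[SummaryStatRecord], config: ClumpConfig
) -> list[SummaryStatRecord]:
    """Keep records with ``pvalue < p_threshold`` and MAF >= ``maf_min``.

    Both comparisons follow the strict conventions documented in
    :class:`ClumpConfig`: a p-value exactly at the threshold is excluded;
    records without an EAF cannot be MAF-filtered and are excluded when
    ``maf_min > 0``.
    """
    kept = []
    for rec in records:
        if not (rec.pvalue < config.p_threshold):
            continue
        maf = rec.maf
        if config.maf_min > 0 and (maf is None or maf < config.maf_min):
            continue
        kept.append(rec)
    return kept


def _chrom_key(chrom: str):
    try:
        return (0, int(chrom))
    except ValueError:
        return (1, chrom)


def _pair_r2(ld_r2: Mapping, a: str, b: str) -> float:
    va = ld_r2.get((a, b))
    vb = ld_r2.get((b, a))
    if va is not None and vb is not None and va != vb:
        raise ValueError(f"asymmetric ld_r2 table for pair ({a}, {b})")
    if va is not None:
        return float(va)
    if vb is not None:
        return float(vb)
    return 0.0  # pair absent: treated as unlinked


def ld_clump(
    records: Sequence[SummaryStatRecord],
    config: ClumpConfig,
    ld_r2: Mapping[tuple[str, str], float] | None = None,
) -> list[SummaryStatRecord]:
    """Greedy p-value-ordered LD clumping.

    Repeatedly accept the smallest-p remaining SNP and discard every
    remaining SNP on the same chromosome within ``window_kb`` kilobases
    whose pairwise r^2 with it exceeds ``r2_threshold``.  Without an
    ``ld_r2`` table the clump runs in distance-only mode and removes *all*
    same-chromosome SNPs inside the window (a stricter approximation that
    never under-prunes).  The accepted set is returned in genomic order.
    """
    if ld_r2 is not None:
        for (a, b) in list(ld_r2):
            _pair_r2(ld_r2, a, b)  # validates symmetry eagerly
    window_bp = config.window_kb * 1000
    remaining = sorted(records, key=lambda r: (r.pvalue, r.snp_id))
    accepted: list[SummaryStatRecord] = []
    while remaining:
        best = remaining.pop(0)
        accepted.append(best)
        survivors = []
        for rec in remaining:
            same_window = (rec.chrom == best.chrom
                           and abs(rec.pos - best.pos) <= window_bp)
            if same_window:
                if ld_r2 is None:
                    continue  # distance-only mode: drop
                if _pair_r2(ld_r2, best.snp_id, rec.snp_id) > config.r2_threshold:
                    continue
            survivors.append(rec)
        remaining = survivors
    accepted.sort(key=lambda r: (_chrom_key(r.chrom), r.pos))
    return accepted


def compute_r2(record: SummaryStatRecord, i: int) -> float:
    """Variance in the exposure explained by one SNP.

    Uses the frequency-based formula ``2*EAF*(1-EAF)*beta^2`` for small
    instrument sets (i < 10) and the sample-size-based form
    ``beta^2 / (beta^2 + N*SE^2)`` for i >= 10.
    """
    if record.eaf is None or not (0.0 < record.eaf < 1.0):
        raise DegenerateInputError(f"eaf must be strictly inside (0,1), got {record.eaf}")
    het = 2.0 * record.eaf * (1.0 - record.eaf)
    if i < 10:
        return het * record.beta ** 2
    b2 = record.beta ** 2
    return b2 / (b2 + record.n * record.se ** 2)


def compute_f(r2_total: float, n: float, i: int) -> float:
    """Multi-instrument F statistic ``[R^2/(1-R^2)] * [(N-1-i)/i]``."""
    if not (0.0 <= r2_total < 1.0):
        raise DegenerateInputError(f"r2_total must be in [0,1), got {r2_total}")
    if not n > i + 1:
        raise DegenerateInputError(f"need n > i + 1 (n={n}, i={i})")
    if i < 1:
        raise DegenerateInputError("i must be >= 1")
    return (r2_total / (1.0 - r2_total)) * ((n - 1.0 - i) / i)


def instrument_strength(
    records: Sequence[SummaryStatRecord], n: float | None = None
) -> InstrumentStrength:
    """Set-level strength: per-SNP R^2 (branch chosen by set size), summed."""
    if not records:
        raise DegenerateInputError("empty instrument set")
    i = len(records)
    if n is None:
        n = max(r.n for r in records)
    r2 = tuple(compute_r2(r, i) for r in records)
    r2_total = min(sum(r2), 1.0 - 1e-12)
    return InstrumentStrength(r2, r2_total, compute_f(r2_total, n, i), n, i)


def strength_filter(
    records: Sequence[SummaryStatRecord],
    n: float | None = None,
    f_min: float = 10.0,
) -> list[SummaryStatRecord]:
    """Exclude weak instruments: per-SNP univariate F < ``f_min``.

    The per-SNP F is ``compute_f`` with i = 1 on that SNP's R^2 (formula
    branch still chosen by the size of the candidate set).  SNPs with
    F exactly at ``f_min`` are retained (exclusion is strict less-than).
    """
    i = len(records)
    kept = []
    for rec in records:
        n_rec = rec.n if n is None else n
        f = compute_f(min(compute_r2(rec, i), 1.0 - 1e-12), n_rec, 1)
        if f < f_min:
            log.info("weak instrument %s excluded (F=%.2f < %g)",
                     rec.snp_id, f, f_min)
            continue
        kept.append(rec)
    return kept


def load_confounder_table(path) -> dict[str, list[str]]:
    """Read a confounder-annotation TSV (columns: snp_id, trait)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"snp_id", "trait"} <= set(frame.columns):
        raise ValueError("confounder table needs columns: snp_id, trait")
    table: dict[str, list[str]] = {}
    for snp, trait in zip(frame["snp_id"], frame["trait"]):
        table.setdefault(snp, []).append(trait)
    return table


def filter_confounders(
    records: Sequence[SummaryStatRecord],
    exclusion_table: Mapping[str, Sequence[str]],
) -> list[SummaryStatRecord]:
    """Drop SNPs annotated to confounder traits (HDL, smoking, BMI, ...).

    The table maps SNP id -> list of confounder trait labels, typically
    exported from a PhenoScanner-style lookup; removals are logged with the
    trait names.
    """
    kept = []
    for rec in records:
        traits = exclusion_table.get(rec.snp_id)
        if traits:
            log.info("confounder-associated instrument %s excluded (%s)",
                     rec.snp_id, ", ".join(traits))
            continue
        kept.append(rec)
    return kept
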