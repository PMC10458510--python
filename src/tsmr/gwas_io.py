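"""Reading, writing and harmonizing GWAS summary statistics.

Summary statistics are exchanged as tab- (or comma-) separated tables with
one row per SNP-trait association.  The canonical header is

    snp  chr  pos  effect_allele  other_allele  eaf  beta  se  pval  n

Foreign headers (MiBioGen-style, OpenGWAS-style exports, ...) are adapted
through a ``column_map`` of standard field name -> file column name.

Harmonization places the exposure and outcome effects of each shared SNP on
a common effect-allele orientation (the exposure's), resolving swapped
alleles, strand flips, and palindromic SNPs, as required by the two-sample
design in which exposure and outcome associations come from different
cohorts.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

VALID_ALLELES = frozenset({"A", "C", "G", "T"})
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order for summary-statistics TSVs
CANONICAL_COLUMNS = (
    "snp", "chr", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
)

#: mapping standard field -> canonical column name
_FIELDS = {
    "snp_id": "snp",
    "chrom": "chr",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pval",
    "n": "n",
}

_MANDATORY = ("snp_id", "chrom", "pos", "effect_allele", "other_allele",
              "beta", "se", "pvalue", "n")


class SummaryStatError(ValueError):
    """A record or table violates the summary-statistics contract."""


class NoInstrumentsError(RuntimeError):
    """No instruments survive harmonization (empty exposure/outcome overlap)."""


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's association with one trait.

    ``beta`` is the per-effect-allele effect (log odds for binary traits),
    ``eaf`` the effect-allele frequency (may be ``None`` when the source
    does not report it, e.g. some outcome GWAS exports).
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pvalue: float
    n: float

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise SummaryStatError(f"invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise SummaryStatError(f"invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise SummaryStatError("effect and other allele must differ")
        if not (self.pos >= 1):
            raise SummaryStatError(f"pos must be >= 1, got {self.pos}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise SummaryStatError(f"eaf out of [0,1]: {self.eaf}")
        if not (self.se > 0 and math.isfinite(self.se)):
            raise SummaryStatError(f"se must be positive and finite, got {self.se}")
        if not (0.0 < self.pvalue <= 1.0):
            raise SummaryStatError(f"pvalue out of (0,1]: {self.pvalue}")
        if not (self.n > 0):
            raise SummaryStatError(f"n must be positive, got {self.n}")
        if not math.isfinite(self.beta):
            raise SummaryStatError(f"beta must be finite, got {self.beta}")

    @property
    def maf(self) -> float | None:
        """Minor-allele frequency, ``min(eaf, 1 - eaf)``."""
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)

    def is_palindromic(self) -> bool:
        """True for A/T and C/G SNPs, whose strand cannot be read off alleles."""
        return self.other_allele == COMPLEMENT[self.effect_allele]


def read_summary_stats_with_skips(
    path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[list[SummaryStatRecord], list[tuple[int, str]]]:
    """Read a summary-statistics table, returning ``(records, skipped)``.

    ``skipped`` collects ``(line_number, reason)`` for every row rejected by
    a type invariant (line numbers count the header as line 1).  A missing
    mandatory column raises :class:`SummaryStatError` instead, because that
    is a configuration problem, not a data problem.
    """
    colmap = dict(_FIELDS)
    if column_map:
        colmap.update({k: v for k, v in column_map.items() if k in _FIELDS})
    table = pd.read_csv(path, sep=None, engine="python", dtype=str,
                        keep_default_na=False)
    missing = [colmap[f] for f in _MANDATORY if colmap[f] not in table.columns]
    if missing:
        raise SummaryStatError(f"missing mandatory column(s): {missing}")
    has_eaf = colmap["eaf"] in table.columns

    records: list[SummaryStatRecord] = []
    skipped: list[tuple[int, str]] = []
    for idx, row in enumerate(table.itertuples(index=False), start=2):
        rowd = dict(zip(table.columns, row))
        try:
            eaf_raw = rowd[colmap["eaf"]] if has_eaf else ""
            eaf = float(eaf_raw) if eaf_raw not in ("", "NA", "nan") else None
            rec = SummaryStatRecord(
                snp_id=str(rowd[colmap["snp_id"]]),
                chrom=str(rowd[colmap["chrom"]]),
                pos=int(float(rowd[colmap["pos"]])),
                effect_allele=str(rowd[colmap["effect_allele"]]).upper(),
                other_allele=str(rowd[colmap["other_allele"]]).upper(),
                eaf=eaf,
                beta=float(rowd[colmap["beta"]]),
                se=float(rowd[colmap["se"]]),
                pvalue=float(rowd[colmap["pvalue"]]),
                n=float(rowd[colmap["n"]]),
            )
        except (SummaryStatError, ValueError) as exc:
            skipped.append((idx, str(exc)))
            continue
        records.append(rec)
    if skipped:
        log.warning("%s: skipped %d invalid row(s): lines %s",
                    path, len(skipped), [ln for ln, _ in skipped])
    return records, skipped


def read_summary_stats(
    path, column_map: Mapping[str, str] | None = None
) -> list[SummaryStatRecord]:
    """Read and validate a summary-statistics table (invalid rows logged and skipped)."""
    records, _ = read_summary_stats_with_skips(path, column_map)
    return records


def write_summary_stats(records: Sequence[SummaryStatRecord], path) -> None:
    """Write records as a canonical-header TSV at full floating precision."""
    frame = pd.DataFrame(
        {
            "snp": [r.snp_id for r in records],
            "chr": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "effect_allele": [r.effect_allele for r in records],
            "other_allele": [r.other_allele for r in records],
            "eaf": [r.eaf if r.eaf is not None else "" for r in records],
            "beta": [repr(r.beta) for r in records],
            "se": [repr(r.se) for r in records],
            "pval": [repr(r.pvalue) for r in records],
            "n": [r.n for r in records],
        },
        columns=list(CANONICAL_COLUMNS),
    )
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

_HARMONIZED_COLUMNS = (
    "snp_id", "chrom", "pos", "beta_exposure", "se_exposure",
    "beta_outcome", "se_outcome", "eaf_exposure", "eaf_outcome",
)


@dataclass
class HarmonizedInstrumentSet:
    """Exposure/outcome effects for a selected instrument set, on the
    exposure's effect-allele orientation.

    ``records`` is a DataFrame with one row per SNP and columns
    ``snp_id, chrom, pos, beta_exposure, se_exposure, beta_outcome,
    se_outcome, eaf_exposure, eaf_outcome``.  ``drops`` records every SNP
    removed during harmonization as ``(snp_id, reason)``.
    """

    records: pd.DataFrame
    exposure_label: str = "exposure"
    outcome_label: str = "outcome"
    n_exposure: float = float("nan")
    n_outcome: float = float("nan")
    drops: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.records) < 1:
            raise NoInstrumentsError("no instruments after harmonization")
        ids = self.records["snp_id"]
        if ids.duplicated().any():
            raise SummaryStatError("duplicate SNP id in harmonized set")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.records["snp_id"].to_numpy()

    @property
    def beta_exposure(self) -> np.ndarray:
        return self.records["beta_exposure"].to_numpy(dtype=float)

    @property
    def se_exposure(self) -> np.ndarray:
        return self.records["se_exposure"].to_numpy(dtype=float)

    @property
    def beta_outcome(self) -> np.ndarray:
        return self.records["beta_outcome"].to_numpy(dtype=float)

    @property
    def se_outcome(self) -> np.ndarray:
        return self.records["se_outcome"].to_numpy(dtype=float)

    @property
    def eaf_exposure(self) -> np.ndarray:
        return self.records["eaf_exposure"].to_numpy(dtype=float)

    @classmethod
    def from_arrays(
        cls,
        beta_exposure,
        se_exposure,
        beta_outcome,
        se_outcome,
        eaf_exposure=None,
        snp_ids=None,
        exposure_label: str = "exposure",
        outcome_label: str = "outcome",
        n_exposure: float = float("nan"),
        n_outcome: float = float("nan"),
    ) -> "HarmonizedInstrumentSet":
        """Build a set directly from effect arrays (simulation / testing path)."""
        bx = np.asarray(beta_exposure, dtype=float)
        j = bx.size
        if snp_ids is None:
            snp_ids = [f"snp{k}" for k in range(j)]
        if eaf_exposure is None:
            eaf_exposure = np.full(j, np.nan)
        frame = pd.DataFrame({
            "snp_id": snp_ids,
            "chrom": ["1"] * j,
            "pos": np.arange(1, j + 1),
            "beta_exposure": bx,
            "se_exposure": np.asarray(se_exposure, dtype=float),
            "beta_outcome": np.asarray(beta_outcome, dtype=float),
            "se_outcome": np.asarray(se_outcome, dtype=float),
            "eaf_exposure": np.asarray(eaf_exposure, dtype=float),
            "eaf_outcome": np.full(j, np.nan),
        })
        return cls(frame, exposure_label, outcome_label, n_exposure, n_outcome)


def _dedupe(records: Iterable[SummaryStatRecord]) -> dict[str, SummaryStatRecord]:
    """Key records by SNP id, keeping the smallest-p record per id."""
    out: dict[str, SummaryStatRecord] = {}
    for rec in records:
        prev = out.get(rec.snp_id)
        if prev is None or rec.pvalue < prev.pvalue:
            if prev is not None:
                log.info("duplicate id %s: keeping p=%.3g, dropping p=%.3g",
                         rec.snp_id, rec.pvalue, prev.pvalue)
            out[rec.snp_id] = rec
        elif prev is not None:
            log.info("duplicate id %s: dropping p=%.3g", rec.snp_id, rec.pvalue)
    return out


def _orient_outcome(exp: SummaryStatRecord, out: SummaryStatRecord,
                    palindromic_eaf_limit: float):
    """Return (beta_outcome, eaf_outcome, reason) for one shared SNP.

    ``reason`` is None when the pair is usable, else a drop reason code.
    """
    e_ea, e_oa = exp.effect_allele, exp.other_allele
    o_ea, o_oa = out.effect_allele, out.other_allele

    if exp.is_palindromic():
        # allele letters cannot distinguish strand flip from allele swap
        if {o_ea, o_oa} != {e_ea, e_oa}:
            return None, None, "incompatible_alleles"
        if out.eaf is None or exp.eaf is None:
            return None, None, "palindromic_missing_eaf"
        if o_ea == e_ea:
            beta, eaf = out.beta, out.eaf
        else:
            beta, eaf = -out.beta, 1.0 - out.eaf
        same_side = (exp.eaf - 0.5) * (eaf - 0.5) > 0
        limit_ok = (min(exp.eaf, 1 - exp.eaf) < palindromic_eaf_limit
                    and min(eaf, 1 - eaf) < palindromic_eaf_limit)
        if same_side and limit_ok:
            return beta, eaf, None
        return None, None, "palindromic_ambiguous"

    for flip_strand in (False, True):
        if flip_strand:
            try:
                a_ea, a_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]
            except KeyError:
                return None, None, "incompatible_alleles"
        else:
            a_ea, a_oa = o_ea, o_oa
        if (a_ea, a_oa) == (e_ea, e_oa):
            return out.beta, out.eaf, None
        if (a_ea, a_oa) == (e_oa, e_ea):
            eaf = None if out.eaf is None else 1.0 - out.eaf
            return -out.beta, eaf, None
    return None, None, "incompatible_alleles"


def harmonize(
    exposure: Sequence[SummaryStatRecord],
    outcome: Sequence[SummaryStatRecord],
    palindromic_eaf_limit: float = 0.42,
    exposure_label: str = "exposure",
    outcome_label: str = "outcome",
    n_exposure: float | None = None,
    n_outcome: float | None = None,
) -> HarmonizedInstrumentSet:
    """Pair exposure and outcome records on the exposure's effect allele.

    Rules, applied per SNP shared by both traits:

    * identical alleles -> kept as-is;
    * swapped alleles -> outcome beta negated, outcome EAF replaced by 1-EAF;
    * strand flip (both alleles complemented) -> complemented before matching;
    * palindromic SNPs (A/T, C/G) -> kept only when both traits' EAFs fall on
      the same side of 0.5 and both MAFs are below ``palindromic_eaf_limit``
      (strand inferred from frequency), otherwise dropped;
    * anything else -> dropped with a reason code recorded in ``drops``.

    Raises :class:`NoInstrumentsError` when nothing survives.
    """
    if not (0.0 < palindromic_eaf_limit < 0.5):
        raise ValueError("palindromic_eaf_limit must be in (0, 0.5)")

    exp_by_id = _dedupe(exposure)
    out_by_id = _dedupe(outcome)

    rows = []
    drops: list[tuple[str, str]] = []
    for snp_id, exp in exp_by_id.items():
        out = out_by_id.get(snp_id)
        if out is None:
            drops.append((snp_id, "not_in_outcome"))
            continue
        beta_o, eaf_o, reason = _orient_outcome(exp, out, palindromic_eaf_limit)
        if reason is not None:
            drops.append((snp_id, reason))
            log.info("harmonize: dropped %s (%s)", snp_id, reason)
            continue
        rows.append({
            "snp_id": snp_id,
            "chrom": exp.chrom,
            "pos": exp.pos,
            "beta_exposure": exp.beta,
            "se_exposure": exp.se,
            "beta_outcome": beta_o,
            "se_outcome": out.se,
            "eaf_exposure": exp.eaf if exp.eaf is not None else np.nan,
            "eaf_outcome": eaf_o if eaf_o is not None else np.nan,
        })
    if not rows:
        raise NoInstrumentsError(
            f"no instruments after harmonization "
            f"({exposure_label} vs {outcome_label})")
    frame = pd.DataFrame(rows, columns=list(_HARMONIZED_COLUMNS))
    if n_exposure is None:
        n_exposure = float(max(r.n for r in exp_by_id.values()))
    if n_outcome is None:
        n_outcome = float(max(r.n for r in out_by_id.values()))
    return HarmonizedInstrumentSet(
        frame, exposure_label, outcome_label, n_exposure, n_outcome, drops)


def write_harmonized(hset: HarmonizedInstrumentSet, path) -> None:
    """Write a harmonized set as TSV with ``#key=value`` metadata lines."""
    with open(path, "w") as fh:
        fh.write(f"#exposure_label={hset.exposure_label}\n")
        fh.write(f"#outcome_label={hset.outcome_label}\n")
        fh.write(f"#n_exposure={hset.n_exposure!r}\n")
        fh.write(f"#n_outcome={hset.n_outcome!r}\n")
        hset.records.to_csv(fh, sep="\t", index=False)


def read_harmonized(path) -> HarmonizedInstrumentSet:
    """Read a harmonized set written by :func:`write_harmonized`."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key] = value
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        frame = pd.read_csv(fh, sep="\t", dtype={"snp_id": str, "chrom": str})
    return HarmonizedInstrumentSet(
        frame,
        exposure_label=meta.get("exposure_label", "exposure"),
        outcome_label=meta.get("outcome_label", "outcome"),
        n_exposure=float(meta.get("n_exposure", "nan")),
        n_outcome=float(meta.get("n_outcome", "nan")),
    )
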