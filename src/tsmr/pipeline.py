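"""End-to-end study orchestration: many exposures x two outcomes.

For every exposure-outcome pair the pipeline runs
select -> harmonize -> estimate (all methods the instrument count permits)
-> sensitivity panel -> Steiger -> Bonferroni by the exposure's category,
and emits one tidy row per (exposure, outcome, method) plus a status row
for any pair that fails a stage (failures are isolated per pair; a sweep
over hundreds of taxa must not abort on one degenerate exposure).
"""
from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import estimators, gwas_io, instruments, sensitivity

log = logging.getLogger(__name__)

#: column order of the tidy result table
RESULT_COLUMNS = (
    "exposure", "category", "outcome", "status", "n_snp", "method",
    "b", "se", "p", "or_", "ci_low", "ci_high",
    "q", "q_df", "q_p", "egger_intercept", "egger_intercept_p",
    "steiger_direction", "steiger_p", "initial_positive",
    "bonferroni_threshold", "passes_correction",
)


@dataclass(frozen=True)
class ExposureSpec:
    label: str
    category: str
    path: str


@dataclass(frozen=True)
class OutcomeSpec:
    label: str
    path: str
    n: float | None = None
    case_fraction: float | None = None


@dataclass
class StudyConfig:
    """Everything needed to run a study reproducibly."""

    exposures: list[ExposureSpec]
    outcomes: list[OutcomeSpec]
    clump: instruments.ClumpConfig = field(
        default_factory=instruments.ClumpConfig)
    correction: Mapping[str, sensitivity.CorrectionScheme] = field(
        default_factory=lambda: dict(sensitivity.DEFAULT_SCHEMES))
    n_boot: int = 1000
    phi: float = 1.0
    seed: int = 0
    palindromic_eaf_limit: float = 0.42
    f_min: float = 10.0
    confounder_path: str | None = None
    column_map: Mapping[str, str] | None = None
    output_dir: str = "."

    def __post_init__(self) -> None:
        labels = [e.label for e in self.exposures] + [o.label for o in self.outcomes]
        if len(set(labels)) != len(labels):
            raise ValueError("exposure/outcome labels must be unique")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for exp in self.exposures:
            if exp.category not in self.correction:
                raise ValueError(
                    f"exposure {exp.label!r}: unknown category {exp.category!r} "
                    f"(no correction scheme configured)")


def load_config(path) -> StudyConfig:
    """Build a :class:`StudyConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    exposures = [ExposureSpec(e["label"], e["category"], e["path"])
                 for e in raw["exposures"]]
    outcomes = [OutcomeSpec(o["label"], o["path"], o.get("n"),
                            o.get("case_fraction"))
                for o in raw["outcomes"]]
    clump = instruments.ClumpConfig(**raw.get("clump", {}))
    correction = {
        cat: sensitivity.CorrectionScheme(cat, int(div))
        for cat, div in raw.get(
            "correction",
            {c: s.divisor for c, s in sensitivity.DEFAULT_SCHEMES.items()}
        ).items()
    }
    est = raw.get("estimators", {})
    return StudyConfig(
        exposures=exposures,
        outcomes=outcomes,
        clump=clump,
        correction=correction,
        n_boot=int(est.get("n_boot", 1000)),
        phi=float(est.get("phi", 1.0)),
        seed=int(raw["seed"]),
        palindromic_eaf_limit=float(raw.get("palindromic_eaf_limit", 0.42)),
        f_min=float(raw.get("f_min", 10.0)),
        confounder_path=raw.get("confounders"),
        column_map=raw.get("column_map"),
        output_dir=raw.get("output_dir", "."),
    )


def _pair_seed(seed: int, exposure: str, outcome: str) -> int:
    # deterministic per-pair substream; crc32 keeps it reproducible across runs
    return int(np.random.SeedSequence(
        [seed, zlib.crc32(f"{exposure}|{outcome}".encode())]
    ).generate_state(1)[0] % (2 ** 31))


def _status_row(exp: ExposureSpec, out: OutcomeSpec, status: str) -> dict:
    row = {c: np.nan for c in RESULT_COLUMNS}
    row.update(exposure=exp.label, category=exp.category, outcome=out.label,
               status=status, method="status", n_snp=0)
    return row


def select_instruments(records, config: StudyConfig,
                       confounder_table=None, ld_r2=None):
    """Threshold -> confounder exclusion -> LD clump -> weak-instrument filter."""
    sel = instruments.threshold_filter(records, config.clump)
    if confounder_table:
        sel = instruments.filter_confounders(sel, confounder_table)
    sel = instruments.ld_clump(sel, config.clump, ld_r2)
    sel = instruments.strength_filter(sel, f_min=config.f_min)
    return sel


def run_study(config: StudyConfig, ld_r2=None) -> pd.DataFrame:
    """Run the full study; returns the tidy result table.

    Every configured exposure appears exactly once per outcome, either as
    a block of method rows (status ``ok``) or as a single status row
    naming the failed stage.
    """
    confounder_table = (instruments.load_confounder_table(config.confounder_path)
                        if config.confounder_path else None)
    rows: list[dict] = []
    failures: list[str] = []
    for out in config.outcomes:
        outcome_records = gwas_io.read_summary_stats(out.path, config.column_map)
        for exp in config.exposures:
            try:
                rows.extend(_run_pair(exp, out, outcome_records,
                                      config, confounder_table, ld_r2))
            except Exception as exc:  # failure isolation per pair
                log.warning("pair (%s, %s) failed: %s", exp.label, out.label, exc)
                failures.append(f"{exp.label} vs {out.label}: {exc}")
                rows.append(_status_row(exp, out, f"error: {exc}"))
    if failures:
        log.warning("study finished with %d failed pair(s)", len(failures))
    frame = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
    frame.attrs["failures"] = failures
    return frame


def _run_pair(exp: ExposureSpec, out: OutcomeSpec, outcome_records,
              config: StudyConfig, confounder_table, ld_r2) -> list[dict]:
    exposure_records = gwas_io.read_summary_stats(exp.path, config.column_map)
    sel = select_instruments(exposure_records, config, confounder_table, ld_r2)
    if not sel:
        return [_status_row(exp, out, "no instruments after selection")]
    try:
        hset = gwas_io.harmonize(
            sel, outcome_records,
            palindromic_eaf_limit=config.palindromic_eaf_limit,
            exposure_label=exp.label, outcome_label=out.label,
            n_outcome=out.n)
    except gwas_io.NoInstrumentsError:
        return [_status_row(exp, out, "no instruments after harmonization")]

    pair_seed = _pair_seed(config.seed, exp.label, out.label)
    ests = estimators.all_estimates(hset, n_boot=config.n_boot,
                                    phi=config.phi, seed=pair_seed)
    ivw_est = ests[0]
    initial_positive = ivw_est.pvalue < 0.05

    egger = (estimators.mr_egger(hset) if len(hset) >= 3 else None)
    outcome_type = "binary" if out.case_fraction is not None else "continuous"
    report = sensitivity.sensitivity_report(
        hset, ivw_est.b, egger, config.correction[exp.category],
        ivw_est.pvalue, outcome_type=outcome_type)

    rows = []
    for est in ests:
        if est.method == "MR Egger" and report.q_egger is not None:
            q, q_df, q_p = (report.q_egger.q, report.q_egger.df,
                            report.q_egger.p)
        elif est.method in ("IVW", "Wald ratio") and report.q_ivw is not None:
            q, q_df, q_p = report.q_ivw.q, report.q_ivw.df, report.q_ivw.p
        else:
            q = q_df = q_p = np.nan
        rows.append({
            "exposure": exp.label, "category": exp.category,
            "outcome": out.label, "status": "ok",
            "n_snp": est.n_snp, "method": est.method,
            "b": est.b, "se": est.se, "p": est.pvalue,
            "or_": est.or_, "ci_low": est.ci_low, "ci_high": est.ci_high,
            "q": q, "q_df": q_df, "q_p": q_p,
            "egger_intercept": report.egger_intercept,
            "egger_intercept_p": report.egger_intercept_p,
            "steiger_direction": report.steiger_direction,
            "steiger_p": report.steiger_p,
            "initial_positive": initial_positive,
            "bonferroni_threshold": report.bonferroni_threshold,
            "passes_correction": report.passes_correction,
        })
    return rows


def write_report(rows: pd.DataFrame, path) -> Path:
    """Write the tidy TSV (full precision) plus a grouped display table.

    The display table (``<stem>_pretty.txt``) rounds to 3 decimals and
    groups rows as exposure blocks with their sensitivity columns; the TSV
    keeps full precision and reloads to the identical frame.
    """
    if len(rows) == 0:
        raise ValueError("no rows to report")
    path = Path(path)
    rows.to_csv(path, sep="\t", index=False)

    pretty = path.with_name(path.stem + "_pretty.txt")
    with open(pretty, "w") as fh:
        for (exp, out), block in rows.groupby(["exposure", "outcome"],
                                              sort=False):
            first = block.iloc[0]
            fh.write(f"== {exp} -> {out} "
                     f"[{first['category']}, status: {first['status']}]\n")
            if first["status"] != "ok":
                fh.write("   (no estimates)\n\n")
                continue
            fh.write(f"   nSNP={int(first['n_snp'])}  "
                     f"Steiger direction={bool(first['steiger_direction'])}  "
                     f"Bonferroni threshold={first['bonferroni_threshold']:.3g}  "
                     f"passes={bool(first['passes_correction'])}\n")
            for _, r in block.iterrows():
                qtxt = ("" if pd.isna(r["q"]) else
                        f"  Q={r['q']:.3f} (df={int(r['q_df'])}, p={r['q_p']:.3f})")
                fh.write(f"   {r['method']:<16} b={r['b']:.3f} SE={r['se']:.3f} "
                         f"p={r['p']:.3f} OR={r['or_']:.3f} "
                         f"95%CI {r['ci_low']:.3f}-{r['ci_high']:.3f}{qtxt}\n")
            icpt = first["egger_intercept"]
            if pd.notna(icpt):
                fh.write(f"   Egger intercept={icpt:.3g} "
                         f"(p={first['egger_intercept_p']:.3f})\n")
            fh.write("\n")
    return pretty


def read_report(path) -> pd.DataFrame:
    """Reload a tidy result TSV written by :func:`write_report`."""
    return pd.read_csv(path, sep="\t")
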