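"""Study orchestration: screens, replication meta-analysis and reports.

A :class:`StudyConfig` (usually loaded from YAML) names the exposure,
mediator and outcome summary-statistic files plus thresholds and seeds.
The screen runs, for every exposure/outcome pair: instrument selection
and harmonization, the five-method estimator suite, the sensitivity
suite with MR-PRESSO remove-and-rerun, the robustness gate, grouped BH
correction within the configured families, and the two-tier association
call.  Per-pair failures are quarantined so one degenerate exposure
cannot abort a multi-taxon screen.  Reports are wide TSV tables plus a
JSON manifest carrying a config hash and seeds for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .estimators import direction_consistent, run_all_methods
from .instruments import InsufficientInstrumentsError, build_harmonized
from .meta import bh_adjust, classify_association, meta_combine
from .sensitivity import run_sensitivity, sensitivity_gate
from .sumstats import LDTable, SummaryStats, read_ld_table, read_sumstats

logger = logging.getLogger(__name__)


@dataclass
class TraitSpec:
    path: str
    label: str
    trait_type: str = "continuous"
    group: str = ""       # FDR family label (e.g. taxonomic rank)
    phenotype: str = ""   # shared phenotype label across replication cohorts


@dataclass
class StudyConfig:
    exposures: list[TraitSpec]
    outcomes: list[TraitSpec]
    mediators: list[TraitSpec] = field(default_factory=list)
    p_threshold_primary: float = 1e-5
    p_threshold_strict: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: int = 10_000
    f_min: float = 10.0
    ld_path: str | None = None
    exclusion_path: str | None = None
    seed: int = 0
    presso_sims: int = 1000
    out_dir: str = "results"

    def __post_init__(self) -> None:
        for thr in (self.p_threshold_primary, self.p_threshold_strict):
            if not 0.0 < thr < 1.0:
                raise ValueError(f"p-threshold must be in (0,1), got {thr}")
        if not self.exposures or not self.outcomes:
            raise ValueError("need at least one exposure and one outcome")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("exposures", "outcomes", "mediators"):
            if key in raw:
                raw[key] = [TraitSpec(**t) for t in raw[key]]
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def load_ld(self) -> LDTable | None:
        return read_ld_table(self.ld_path) if self.ld_path else None

    def load_exclusions(self) -> tuple[str, ...]:
        if not self.exclusion_path:
            return ()
        text = Path(self.exclusion_path).read_text()
        return tuple(line.strip() for line in text.splitlines() if line.strip())


def _load(spec: TraitSpec) -> SummaryStats:
    return read_sumstats(spec.path, spec.label, spec.trait_type)


def _screen_pair(exposure: SummaryStats, outcome: SummaryStats, group: str,
                 p_threshold: float, ld, exclude, f_min: float,
                 seed: int, presso_sims: int,
                 strict_mode: bool = False) -> dict:
    """One exposure/outcome record: estimates + sensitivity + gate."""
    record: dict = {
        "exposure": exposure.trait_name,
        "outcome": outcome.trait_name,
        "group": group or "ungrouped",
        "p_threshold": p_threshold,
        "status": "ok",
        "skip_reason": "",
    }
    try:
        h, log = build_harmonized(exposure, outcome, p_threshold=p_threshold,
                                  ld=ld, f_min=f_min, exclude=exclude)
    except InsufficientInstrumentsError as exc:
        record.update(status="skipped", skip_reason=str(exc))
        return record
    report, h_used = run_sensitivity(h, n_sim=presso_sims, seed=seed) \
        if h.k >= 2 else (None, h)
    estimates = run_all_methods(h_used, seed=seed)
    ivw_est = estimates[0]
    record.update(
        k=h_used.k,
        selection_log=json.dumps(log),
        method=ivw_est.method,
        beta=ivw_est.beta,
        se=ivw_est.se,
        pvalue=ivw_est.pvalue,
        or_value=ivw_est.or_value,
        ci_low=ivw_est.ci_low,
        ci_high=ivw_est.ci_high,
        model_note=ivw_est.model_note,
        direction_consistent=direction_consistent(estimates),
        all_methods=json.dumps({e.method: round(e.beta, 6) for e in estimates}),
    )
    if strict_mode and (h_used.k < 2 or report is None):
        record["confirmation"] = "unconfirmed"
    if report is not None:
        robust, verdict, note = sensitivity_gate(estimates, report)
        record.update(
            q_value=report.q_value,
            q_pvalue=report.q_pvalue,
            egger_intercept=report.egger_intercept,
            egger_intercept_p=report.egger_intercept_p,
            presso_global_p=report.presso_global_p,
            presso_outliers=",".join(sorted(report.presso_outliers)),
            loo_flagged=",".join(sorted(report.loo_flagged)),
            robust=robust,
            verdict=verdict,
            gate_note=note,
        )
    else:
        record.update(robust=None, verdict="unconfirmed",
                      gate_note="too_few_snps_for_sensitivity")
    return record


def _attach_fdr(records: list[dict]) -> None:
    """Grouped BH over the IVW p-values, then the two-tier call, in place."""
    scored = [r for r in records if r.get("status") == "ok"]
    if not scored:
        return
    pvals = [r["pvalue"] for r in scored]
    groups = [f"{r['group']}|{r['outcome']}" for r in scored]
    adj = bh_adjust(pvals, groups)
    for r, p_fdr in zip(scored, adj):
        call = classify_association(r["pvalue"], float(p_fdr), r["group"])
        r["p_fdr"] = float(p_fdr)
        r["call"] = call.call


def run_forward_screen(cfg: StudyConfig, strict: bool = False) -> list[dict]:
    """Screen every exposure against every outcome at the configured threshold."""
    ld = cfg.load_ld()
    exclude = cfg.load_exclusions()
    threshold = cfg.p_threshold_strict if strict else cfg.p_threshold_primary
    outcomes = [_load(o) for o in cfg.outcomes]
    records: list[dict] = []
    for espec in cfg.exposures:
        try:
            exposure = _load(espec)
        except Exception as exc:  # quarantine malformed inputs
            logger.error("failed to load %s: %s", espec.label, exc)
            records.append({"exposure": espec.label, "outcome": "*",
                            "group": espec.group or "ungrouped",
                            "status": "failed", "skip_reason": str(exc)})
            continue
        for outcome in outcomes:
            records.append(_screen_pair(
                exposure, outcome, espec.group, threshold, ld, exclude,
                cfg.f_min, cfg.seed, cfg.presso_sims, strict_mode=strict))
    _attach_fdr(records)
    return records


def run_strict_threshold(cfg: StudyConfig) -> list[dict]:
    """Forward screen at the genome-wide threshold; single-SNP pairs use Wald."""
    return run_forward_screen(cfg, strict=True)


def run_reverse(cfg: StudyConfig,
                selected_pairs: Sequence[tuple[str, str]] | None = None) -> list[dict]:
    """Reverse MR: outcomes as exposures, exposures as outcomes.

    ``selected_pairs`` restricts to (exposure_label, outcome_label)
    pairs from the forward screen; default reverses everything.
    """
    ld = cfg.load_ld()
    exclude = cfg.load_exclusions()
    wanted = set(selected_pairs) if selected_pairs else None
    records: list[dict] = []
    exposures = {e.label: (_load(e), e) for e in cfg.exposures}
    for ospec in cfg.outcomes:
        outcome_as_exposure = _load(ospec)
        for label, (orig_exposure, espec) in exposures.items():
            if wanted is not None and (label, ospec.label) not in wanted:
                continue
            records.append(_screen_pair(
                outcome_as_exposure, orig_exposure, ospec.group,
                cfg.p_threshold_primary, ld, exclude, cfg.f_min,
                cfg.seed, cfg.presso_sims))
    _attach_fdr(records)
    return records


def run_replication_meta(cfg: StudyConfig, model: str = "fixed") -> list[dict]:
    """Per-exposure IVW in each replication cohort, pooled by meta-analysis.

    Cohorts are outcomes sharing a ``phenotype`` label.  An exposure
    retains causality iff the pooled p is below 0.05.
    """
    ld = cfg.load_ld()
    exclude = cfg.load_exclusions()
    by_pheno: dict[str, list[TraitSpec]] = {}
    for o in cfg.outcomes:
        by_pheno.setdefault(o.phenotype or o.label, []).append(o)
    records: list[dict] = []
    for espec in cfg.exposures:
        exposure = _load(espec)
        for pheno, cohort_specs in by_pheno.items():
            if len(cohort_specs) < 2:
                continue
            per_cohort = []
            for ospec in cohort_specs:
                outcome = _load(ospec)
                try:
                    h, _ = build_harmonized(
                        exposure, outcome, p_threshold=cfg.p_threshold_primary,
                        ld=ld, f_min=cfg.f_min, exclude=exclude)
                except InsufficientInstrumentsError:
                    continue
                est = run_all_methods(h, seed=cfg.seed)[0]
                per_cohort.append((ospec.label, est))
            if len(per_cohort) < 2:
                records.append({"exposure": espec.label, "phenotype": pheno,
                                "status": "skipped",
                                "skip_reason": "fewer than two cohort estimates"})
                continue
            meta = meta_combine([(e.beta, e.se) for _, e in per_cohort], model=model)
            records.append({
                "exposure": espec.label,
                "phenotype": pheno,
                "status": "ok",
                "cohorts": ",".join(lbl for lbl, _ in per_cohort),
                "cohort_betas": json.dumps({lbl: round(e.beta, 6)
                                            for lbl, e in per_cohort}),
                "cohort_ses": json.dumps({lbl: round(e.se, 6)
                                          for lbl, e in per_cohort}),
                "pooled_beta": meta.pooled_beta,
                "pooled_se": meta.pooled_se,
                "pooled_p": meta.pooled_p,
                "or_value": meta.or_value,
                "ci_low": meta.ci_low,
                "ci_high": meta.ci_high,
                "q_value": meta.q_value,
                "q_pvalue": meta.q_pvalue,
                "i_squared": meta.i_squared,
                "model": meta.model,
                "retained": meta.pooled_p < 0.05,
            })
    return records


REPORT_COLUMNS = [
    "exposure", "outcome", "group", "status", "skip_reason", "k", "method",
    "beta", "se", "pvalue", "p_fdr", "or_value", "ci_low", "ci_high", "call",
    "model_note", "direction_consistent", "q_value", "q_pvalue",
    "egger_intercept", "egger_intercept_p", "presso_global_p",
    "presso_outliers", "loo_flagged", "robust", "verdict", "gate_note",
    "selection_log", "all_methods",
]


def render_report(records_by_stage: dict[str, list[dict]],
                  out_dir: str | Path, cfg: StudyConfig | None = None) -> dict:
    """Write one wide TSV per stage plus a reproducibility manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for stage, records in records_by_stage.items():
        df = pd.DataFrame.from_records(records)
        if df.empty:
            df = pd.DataFrame(columns=REPORT_COLUMNS)
        else:
            lead = [c for c in REPORT_COLUMNS if c in df.columns]
            rest = [c for c in df.columns if c not in lead]
            df = df[lead + rest]
        path = out / f"{stage}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        written[stage] = str(path)
    manifest = {
        "tool": "mrmediate",
        "version": __version__,
        "stages": written,
        "config_hash": cfg.config_hash() if cfg else None,
        "seed": cfg.seed if cfg else None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
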