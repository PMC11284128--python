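"""Instrument selection, filtering and allele harmonization.

The selection pipeline runs in a fixed order:

1. p-value threshold (strict ``<``),
2. greedy LD clumping (r² and physical window),
3. weak-instrument exclusion (per-SNP F < 10),
4. removal of SNPs more strongly associated with the outcome than with
   the exposure (P_outcome < P_exposure),
5. harmonization against the outcome, dropping palindromic (A/T, G/C)
   SNPs outright and sign-flipping outcome effects where the effect
   alleles are swapped (directly or after strand complement),
6. a user-supplied exclusion list (stand-in for confounder lookups).

Selection counts are carried along so the pipeline can report
non-increasing per-step totals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .sumstats import (
    COMPLEMENT,
    LDTable,
    SummaryStats,
    is_palindromic,
)

logger = logging.getLogger(__name__)

LOG_STEPS = [
    "initial",
    "post_threshold",
    "post_clump",
    "post_f",
    "post_outcome_filter",
    "post_palindrome",
    "post_exclusion",
]


class InsufficientInstrumentsError(ValueError):
    """Raised when an operation needs more instruments than are available."""


class EmptyHarmonizedSetError(InsufficientInstrumentsError):
    """No SNP survived harmonization; the pipeline should skip this pair."""


@dataclass
class InstrumentSet:
    """Selected instruments for one exposure, with per-step selection counts."""

    exposure_name: str
    members: pd.DataFrame = field(repr=False)
    selection_log: dict[str, int] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.members)

    def logged(self, step: str) -> "InstrumentSet":
        log = dict(self.selection_log)
        log[step] = self.k
        return InstrumentSet(self.exposure_name, self.members, log)


@dataclass
class HarmonizedSet:
    """Allele-aligned per-SNP exposure/outcome effect pairs.

    The unit every estimator consumes: for SNP j, (beta_x[j], se_x[j])
    is the exposure association and (beta_y[j], se_y[j]) the outcome
    association on the same effect allele.
    """

    exposure_name: str
    outcome_name: str
    variant_id: np.ndarray
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray

    def __post_init__(self) -> None:
        self.variant_id = np.asarray(self.variant_id, dtype=object)
        for name in ("beta_x", "se_x", "beta_y", "se_y"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.k == 0:
            raise EmptyHarmonizedSetError(
                f"no harmonized SNPs for {self.exposure_name} -> {self.outcome_name}"
            )
        if np.any(self.se_x <= 0) or np.any(self.se_y <= 0):
            raise ValueError("all standard errors must be strictly positive")

    @property
    def k(self) -> int:
        return len(self.variant_id)

    def subset(self, mask: np.ndarray) -> "HarmonizedSet":
        mask = np.asarray(mask)
        return HarmonizedSet(
            self.exposure_name,
            self.outcome_name,
            self.variant_id[mask],
            self.beta_x[mask],
            self.se_x[mask],
            self.beta_y[mask],
            self.se_y[mask],
        )

    def drop_ids(self, ids: Iterable[str]) -> "HarmonizedSet":
        drop = set(ids)
        return self.subset(np.array([v not in drop for v in self.variant_id]))


@dataclass
class FStatReport:
    """Instrument-strength report: F = R²(n−1−k) / ((1−R²)k)."""

    r2_total: float
    n: int
    k: int
    f_value: float
    weak: bool


def select_by_pvalue(stats: SummaryStats, threshold: float) -> InstrumentSet:
    """Instruments with association p strictly below ``threshold``.

    Members are ordered by (pvalue, chrom, pos, variant_id) so that
    downstream greedy clumping is deterministic.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    df = stats.records
    kept = df[df["pvalue"] < threshold].sort_values(
        ["pvalue", "chrom", "pos", "variant_id"], kind="mergesort"
    ).reset_index(drop=True)
    if kept.empty:
        logger.info("no instruments for %s at p < %g", stats.trait_name, threshold)
    inst = InstrumentSet(stats.trait_name, kept, {"initial": len(df)})
    return inst.logged("post_threshold")


def clump(
    inst: InstrumentSet,
    ld: LDTable | None,
    r2_max: float = 0.001,
    window_kb: int = 10_000,
) -> InstrumentSet:
    """Greedy LD clumping: keep the best remaining SNP, discard linked neighbours.

    Candidates are ranked by p ascending (ties by chrom, pos, variant_id);
    each index SNP removes same-chromosome SNPs within ±window_kb whose
    r² with it exceeds ``r2_max``.  Missing LD entries count as r² = 0.
    """
    df = inst.members.sort_values(
        ["pvalue", "chrom", "pos", "variant_id"], kind="mergesort"
    ).reset_index(drop=True)
    window_bp = int(window_kb) * 1000
    alive = np.ones(len(df), dtype=bool)
    kept_rows: list[int] = []
    ids = df["variant_id"].to_numpy()
    chroms = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy()
    for i in range(len(df)):
        if not alive[i]:
            continue
        kept_rows.append(i)
        if ld is None:
            continue
        near = alive & (chroms == chroms[i]) & (np.abs(pos - pos[i]) <= window_bp)
        near[i] = False
        for j in np.flatnonzero(near):
            if ld.r2(ids[i], ids[j]) > r2_max:
                alive[j] = False
    out = df.iloc[kept_rows].reset_index(drop=True)
    return InstrumentSet(inst.exposure_name, out, dict(inst.selection_log)).logged(
        "post_clump"
    )


def snp_r2(beta: float, se: float, n: int, eaf: float | None = None,
           method: str = "z") -> float:
    """Per-SNP variance explained.

    Default is the z-score approximation r² = z²/(z² + n − 2), which
    needs no allele frequency.  ``method='eaf'`` uses 2·p(1−p)·β² for a
    standardized continuous trait.
    """
    if method == "eaf":
        if eaf is None or np.isnan(eaf):
            raise ValueError("eaf method requires an allele frequency")
        return float(2.0 * eaf * (1.0 - eaf) * beta**2)
    z = beta / se
    return float(z**2 / (z**2 + n - 2))


def f_statistic(r2_total: float, n: int, k: int) -> FStatReport:
    """Set-level F statistic F = R²(n−1−k)/((1−R²)k); weak if F < 10."""
    if not 0.0 <= r2_total < 1.0:
        raise ValueError(f"r2_total must be in [0,1), got {r2_total}")
    if n <= k + 1 or k < 1:
        raise ValueError(f"need n > k+1 >= 2, got n={n}, k={k}")
    f_value = r2_total * (n - 1 - k) / ((1.0 - r2_total) * k)
    return FStatReport(float(r2_total), int(n), int(k), float(f_value),
                       weak=bool(f_value < 10.0))


def drop_weak_instruments(inst: InstrumentSet, f_min: float = 10.0,
                          r2_method: str = "z") -> InstrumentSet:
    """Exclude SNPs whose single-SNP F statistic falls below ``f_min``.

    With the z-based r², the per-SNP F (k = 1) reduces exactly to z², so
    this is equivalent to requiring |beta/se| >= sqrt(f_min).
    """
    df = inst.members
    keep = []
    for row in df.itertuples(index=False):
        r2 = snp_r2(row.beta, row.se, row.n, row.eaf, method=r2_method)
        f = f_statistic(r2, int(row.n), 1).f_value
        keep.append(f >= f_min)
    out = df[np.array(keep, dtype=bool)].reset_index(drop=True)
    return InstrumentSet(inst.exposure_name, out, dict(inst.selection_log)).logged("post_f")


def set_f_report(inst: InstrumentSet, r2_method: str = "z") -> FStatReport | None:
    """Set-level F using summed per-SNP r² and the median sample size."""
    if inst.k == 0:
        return None
    df = inst.members
    r2_total = sum(
        snp_r2(r.beta, r.se, r.n, r.eaf, method=r2_method)
        for r in df.itertuples(index=False)
    )
    n = int(np.median(df["n"]))
    if n <= inst.k + 1 or r2_total >= 1.0:
        return None
    return f_statistic(r2_total, n, inst.k)


def drop_outcome_associated(inst: InstrumentSet, outcome: SummaryStats) -> InstrumentSet:
    """Remove SNP j iff its outcome p-value is strictly below its exposure p.

    SNPs missing from the outcome pass through (they are dropped later at
    harmonization, with logging).  Equal p-values keep the SNP.
    """
    out_p = outcome.records.set_index("variant_id")["pvalue"]
    df = inst.members
    keep = []
    for row in df.itertuples(index=False):
        p_out = out_p.get(row.variant_id)
        if p_out is None:
            logger.info("%s absent from outcome %s at outcome-p filter",
                        row.variant_id, outcome.trait_name)
            keep.append(True)
        else:
            keep.append(not (p_out < row.pvalue))
    out = df[np.array(keep, dtype=bool)].reset_index(drop=True)
    return InstrumentSet(inst.exposure_name, out,
                         dict(inst.selection_log)).logged("post_outcome_filter")


def apply_exclusion_list(inst: InstrumentSet, excluded_ids: Iterable[str]) -> InstrumentSet:
    """Remove the named SNPs (e.g. confounder-associated variants)."""
    excluded = set(excluded_ids)
    df = inst.members
    present = df["variant_id"].isin(excluded)
    if present.any():
        logger.info("excluding %d SNP(s): %s", int(present.sum()),
                    ", ".join(df.loc[present, "variant_id"]))
    removed_absent = excluded - set(df["variant_id"])
    if removed_absent:
        logger.info("exclusion ids not present: %s", ", ".join(sorted(removed_absent)))
    out = df[~present].reset_index(drop=True)
    return InstrumentSet(inst.exposure_name, out,
                         dict(inst.selection_log)).logged("post_exclusion")


def _align_outcome(exp_ea: str, exp_oa: str, out_row) -> tuple[float, bool] | None:
    """Sign multiplier for the outcome beta given exposure alleles, or None.

    Returns (sign, flipped) where sign multiplies the outcome beta;
    None when the allele sets cannot be reconciled even after strand
    complement.
    """
    oea, ooa = out_row.effect_allele, out_row.other_allele
    if (oea, ooa) == (exp_ea, exp_oa):
        return 1.0, False
    if (oea, ooa) == (exp_oa, exp_ea):
        return -1.0, True
    cea, coa = COMPLEMENT[oea], COMPLEMENT[ooa]
    if (cea, coa) == (exp_ea, exp_oa):
        return 1.0, False
    if (cea, coa) == (exp_oa, exp_ea):
        return -1.0, True
    return None


def harmonize(inst: InstrumentSet, outcome: SummaryStats) -> HarmonizedSet:
    """Align exposure and outcome effects to the same effect allele.

    Palindromic (A/T, G/C) SNPs are dropped unconditionally; SNPs absent
    from the outcome or with irreconcilable alleles are dropped with
    logging.  Raises :class:`EmptyHarmonizedSetError` when nothing
    survives, so callers can skip the pair explicitly.
    """
    out_idx = outcome.records.set_index("variant_id")
    ids, bx, sx, by, sy = [], [], [], [], []
    for row in inst.members.itertuples(index=False):
        if is_palindromic(row.effect_allele, row.other_allele):
            continue
        if row.variant_id not in out_idx.index:
            logger.info("%s absent from outcome %s", row.variant_id, outcome.trait_name)
            continue
        orow = out_idx.loc[row.variant_id]
        aligned = _align_outcome(row.effect_allele, row.other_allele, orow)
        if aligned is None:
            logger.info("%s alleles irreconcilable with outcome %s",
                        row.variant_id, outcome.trait_name)
            continue
        sign, _ = aligned
        ids.append(row.variant_id)
        bx.append(row.beta)
        sx.append(row.se)
        by.append(sign * orow.beta)
        sy.append(orow.se)
    return HarmonizedSet(inst.exposure_name, outcome.trait_name,
                         np.array(ids, dtype=object), np.array(bx), np.array(sx),
                         np.array(by), np.array(sy))


def build_harmonized(
    exposure: SummaryStats,
    outcome: SummaryStats,
    p_threshold: float = 1e-5,
    ld: LDTable | None = None,
    r2_max: float = 0.001,
    window_kb: int = 10_000,
    f_min: float = 10.0,
    exclude: Iterable[str] = (),
    outcome_p_filter: bool = True,
) -> tuple[HarmonizedSet, dict[str, int]]:
    """Run the full instrument pipeline for one exposure/outcome pair.

    Returns the harmonized set and the per-step selection log
    (non-increasing counts).  Raises
    :class:`EmptyHarmonizedSetError` / :class:`InsufficientInstrumentsError`
    when no instrument survives a stage.
    """
    inst = select_by_pvalue(exposure, p_threshold)
    if inst.k == 0:
        raise InsufficientInstrumentsError(
            f"no instruments for {exposure.trait_name} at p < {p_threshold:g}"
        )
    inst = clump(inst, ld, r2_max=r2_max, window_kb=window_kb)
    inst = drop_weak_instruments(inst, f_min=f_min)
    if outcome_p_filter:
        inst = drop_outcome_associated(inst, outcome)
    if inst.k == 0:
        raise InsufficientInstrumentsError(
            f"no instruments left for {exposure.trait_name} after filtering"
        )
    h = harmonize(inst, outcome)
    log = dict(inst.selection_log)
    log["post_palindrome"] = h.k
    if exclude:
        h = h.drop_ids(exclude)
    log["post_exclusion"] = h.k
    return h, log
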