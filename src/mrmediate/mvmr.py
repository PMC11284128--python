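"""Multivariable MR and two-step mediation decomposition.

Multivariable MR (MVMR) regresses SNP-outcome effects jointly on the
SNP-effect columns of several exposures (here: one exposure and one
mediator), with inverse-variance weights 1/se_yj² and no intercept.
Each coefficient is the corresponding trait's *direct* effect on the
outcome, holding the other traits fixed.

The mediation decomposition follows the two-step product-of-
coefficients design:

* beta_total — univariable IVW of exposure on outcome,
* beta_xz    — univariable IVW of exposure on mediator,
* beta_zy    — the mediator's direct effect from MVMR (exposure +
  mediator jointly on outcome),
* mediated effect = beta_xz × beta_zy,
* proportion mediated = mediated effect / beta_total,

and a mediating pathway is considered to exist only when the mediated
effect and the total effect share direction (sign(0) counts as
inconsistent with any nonzero sign).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .estimators import MREstimate, _make_estimate, ivw, p_from_z, wald_ratio
from .instruments import (
    EmptyHarmonizedSetError,
    HarmonizedSet,
    InstrumentSet,
    InsufficientInstrumentsError,
    _align_outcome,
    build_harmonized,
    clump,
    drop_weak_instruments,
    select_by_pvalue,
)
from .sensitivity import SensitivityReport, run_sensitivity
from .sumstats import LDTable, SummaryStats, is_palindromic

logger = logging.getLogger(__name__)


class CollinearityError(ValueError):
    """The MVMR design matrix is rank-deficient."""


class ConvergenceError(RuntimeError):
    """Iteratively reweighted least squares failed to converge."""


@dataclass
class MVHarmonizedSet:
    """Joint instrument matrix: k SNPs × m exposures, aligned per SNP."""

    outcome_name: str
    exposure_names: list[str]
    variant_id: np.ndarray
    beta_x: np.ndarray  # (k, m)
    se_x: np.ndarray    # (k, m)
    beta_y: np.ndarray  # (k,)
    se_y: np.ndarray    # (k,)

    def __post_init__(self) -> None:
        self.variant_id = np.asarray(self.variant_id, dtype=object)
        self.beta_x = np.atleast_2d(np.asarray(self.beta_x, dtype=float))
        self.se_x = np.atleast_2d(np.asarray(self.se_x, dtype=float))
        self.beta_y = np.asarray(self.beta_y, dtype=float)
        self.se_y = np.asarray(self.se_y, dtype=float)
        if self.k <= self.m:
            raise InsufficientInstrumentsError(
                f"MVMR needs k > m, got k={self.k}, m={self.m}"
            )

    @property
    def k(self) -> int:
        return len(self.variant_id)

    @property
    def m(self) -> int:
        return self.beta_x.shape[1]


@dataclass
class MVMRResult:
    """Per-exposure direct-effect estimates from one MVMR fit."""

    method: str
    estimates: dict[str, MREstimate]
    intercept: dict | None = None


@dataclass
class MediationResult:
    """Two-step decomposition of a total effect into mediated and direct parts."""

    beta_total: float
    beta_xz: float
    beta_zy: float
    mediated_effect: float
    proportion_mediated: float
    direction_consistent: bool

    @property
    def proportion_pct(self) -> str:
        return f"{100.0 * self.proportion_mediated:.2f}%"


def mvmr_harmonize(
    instruments: Mapping[str, InstrumentSet],
    exposures: Sequence[SummaryStats],
    outcome: SummaryStats,
    ld: LDTable | None = None,
    r2_max: float = 0.001,
    window_kb: int = 10_000,
) -> MVHarmonizedSet:
    """Build the joint instrument matrix for MVMR.

    Takes the union of every exposure's selected instruments, clumps it
    jointly (ranking by the minimum p across exposures), keeps only SNPs
    present in all exposure and outcome datasets, drops palindromes, and
    aligns every trait to the first exposure's effect allele.
    """
    if len(exposures) < 2:
        raise ValueError("MVMR needs at least two exposures")
    names = [e.trait_name for e in exposures]
    for name in names:
        if name not in instruments:
            raise ValueError(f"no instrument set supplied for exposure {name!r}")

    # union of instruments, ranked by min p across the contributing sets
    best_p: dict[str, float] = {}
    rows: dict[str, object] = {}
    for name in names:
        for row in instruments[name].members.itertuples(index=False):
            if row.variant_id not in best_p or row.pvalue < best_p[row.variant_id]:
                best_p[row.variant_id] = row.pvalue
                rows[row.variant_id] = row
    import pandas as pd

    union = pd.DataFrame([r._asdict() for r in rows.values()])
    union["pvalue"] = [best_p[v] for v in union["variant_id"]]
    union_set = InstrumentSet("mvmr_union", union, {"initial": len(union)})
    union_set = clump(union_set, ld, r2_max=r2_max, window_kb=window_kb)

    exp_idx = [e.records.set_index("variant_id") for e in exposures]
    out_idx = outcome.records.set_index("variant_id")
    ids, bx, sx, by, sy = [], [], [], [], []
    for vid in union_set.members["variant_id"]:
        if vid not in out_idx.index or any(vid not in idx.index for idx in exp_idx):
            logger.info("%s missing from a dataset, dropped from MVMR", vid)
            continue
        ref = exp_idx[0].loc[vid]
        if is_palindromic(ref.effect_allele, ref.other_allele):
            continue
        betas, ses, ok = [], [], True
        for idx in exp_idx:
            row = idx.loc[vid]
            aligned = _align_outcome(ref.effect_allele, ref.other_allele, row)
            if aligned is None:
                ok = False
                break
            betas.append(aligned[0] * row.beta)
            ses.append(row.se)
        if not ok:
            logger.info("%s alleles irreconcilable across exposures", vid)
            continue
        orow = out_idx.loc[vid]
        aligned = _align_outcome(ref.effect_allele, ref.other_allele, orow)
        if aligned is None:
            logger.info("%s alleles irreconcilable with outcome", vid)
            continue
        ids.append(vid)
        bx.append(betas)
        sx.append(ses)
        by.append(aligned[0] * orow.beta)
        sy.append(orow.se)
    if not ids:
        raise EmptyHarmonizedSetError("no SNP survived MVMR harmonization")
    return MVHarmonizedSet(outcome.trait_name, names, np.array(ids, dtype=object),
                           np.array(bx), np.array(sx), np.array(by), np.array(sy))


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray,
         names: Sequence[str]) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted least squares via normal equations, with rank check."""
    Xw = X * np.sqrt(w)[:, None]
    if np.linalg.matrix_rank(Xw) < X.shape[1]:
        corr = np.corrcoef(X, rowvar=False)
        pairs = [
            f"{names[i]}~{names[j]}"
            for i in range(len(names))
            for j in range(i + 1, len(names))
            if abs(corr[i, j]) > 0.999
        ]
        raise CollinearityError(
            "rank-deficient MVMR design" + (f" ({', '.join(pairs)})" if pairs else "")
        )
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * y))
    resid = y - X @ coef
    rss = float(np.sum(w * resid**2))
    return coef, np.linalg.inv(xtwx), rss


def mvmr_ivw(mv: MVHarmonizedSet) -> MVMRResult:
    """Multivariable IVW: weighted multiple regression without intercept.

    SEs carry the multiplicative overdispersion factor
    max(1, sqrt(RSS/(k−m))).
    """
    w = 1.0 / mv.se_y**2
    coef, cov_unit, rss = _wls(mv.beta_x, mv.beta_y, w, mv.exposure_names)
    phi = max(1.0, rss / (mv.k - mv.m))
    ses = np.sqrt(phi * np.diag(cov_unit))
    estimates = {
        name: _make_estimate("mvmr_ivw", coef[i], ses[i], mv.k)
        for i, name in enumerate(mv.exposure_names)
    }
    return MVMRResult("mvmr_ivw", estimates)


def mvmr_egger(mv: MVHarmonizedSet) -> MVMRResult:
    """Multivariable Egger: as IVW plus an intercept for directional pleiotropy.

    SNPs are oriented so the first-listed exposure's betas are
    non-negative.
    """
    if mv.k <= mv.m + 1:
        raise InsufficientInstrumentsError("mvmr_egger needs k > m + 1")
    sign = np.where(mv.beta_x[:, 0] < 0, -1.0, 1.0)
    Xo = mv.beta_x * sign[:, None]
    yo = mv.beta_y * sign
    X = np.column_stack([np.ones(mv.k), Xo])
    w = 1.0 / mv.se_y**2
    coef, cov_unit, rss = _wls(X, yo, w, ["(intercept)"] + mv.exposure_names)
    phi = max(1.0, rss / (mv.k - mv.m - 1))
    ses = np.sqrt(phi * np.diag(cov_unit))
    estimates = {
        name: _make_estimate("mvmr_egger", coef[i + 1], ses[i + 1], mv.k)
        for i, name in enumerate(mv.exposure_names)
    }
    intercept = {
        "intercept": float(coef[0]),
        "intercept_se": float(ses[0]),
        "intercept_p": p_from_z(coef[0], ses[0]),
    }
    return MVMRResult("mvmr_egger", estimates, intercept)


def _irls_l1(X: np.ndarray, y: np.ndarray, w: np.ndarray,
             tol: float = 1e-10, max_iter: int = 5000) -> np.ndarray:
    """Weighted L1 (median) regression by iteratively reweighted least squares."""
    coef = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))
    eps = 1e-8  # smoothing of |r| -> sqrt(r^2 + eps^2) keeps the MM step monotone
    for _ in range(max_iter):
        r = y - X @ coef
        wr = w / np.sqrt(r**2 + eps**2)
        new = np.linalg.solve(X.T @ (wr[:, None] * X), X.T @ (wr * y))
        if np.max(np.abs(new - coef)) < tol * (1.0 + np.max(np.abs(coef))):
            return new
        coef = new
    raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")


def mvmr_median(mv: MVHarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MVMRResult:
    """Multivariable weighted median regression, bootstrap SEs (seeded)."""
    w = 1.0 / mv.se_y**2
    coef = _irls_l1(mv.beta_x, mv.beta_y, w)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, mv.m))
    for b in range(n_boot):
        bx = rng.normal(mv.beta_x, mv.se_x)
        by = rng.normal(mv.beta_y, mv.se_y)
        try:
            boots[b] = _irls_l1(bx, by, w)
        except ConvergenceError:
            boots[b] = np.nan
    ses = np.nanstd(boots, axis=0, ddof=1)
    estimates = {
        name: _make_estimate("mvmr_median", coef[i], ses[i], mv.k)
        for i, name in enumerate(mv.exposure_names)
    }
    return MVMRResult("mvmr_median", estimates)


def mediation_decompose(beta_total: float, beta_xz: float,
                        beta_zy: float) -> MediationResult:
    """Product-of-coefficients decomposition of a total causal effect.

    mediated = beta_xz × beta_zy; proportion = mediated / beta_total;
    the pathway exists only when mediated and total effects share sign.
    """
    if beta_total == 0:
        raise ValueError("mediation undefined for beta_total = 0")
    mediated = beta_xz * beta_zy
    proportion = mediated / beta_total
    consistent = bool(np.sign(mediated) == np.sign(beta_total) and mediated != 0)
    return MediationResult(float(beta_total), float(beta_xz), float(beta_zy),
                           float(mediated), float(proportion), consistent)


@dataclass
class TwoStepConfig:
    """Knobs for the end-to-end two-step mediation analysis."""

    p_threshold: float = 1e-5
    ld: LDTable | None = None
    r2_max: float = 0.001
    window_kb: int = 10_000
    f_min: float = 10.0
    exclude: tuple[str, ...] = ()
    seed: int = 0
    presso_sims: int = 1000
    run_sensitivity: bool = True


@dataclass
class TwoStepResult:
    """Mediation decomposition with all intermediate estimates attached."""

    mediation: MediationResult
    total: MREstimate
    xz: MREstimate
    zy: MREstimate
    mvmr: MVMRResult
    sensitivity: dict[str, SensitivityReport] = field(default_factory=dict)
    logs: dict[str, dict[str, int]] = field(default_factory=dict)


def _uvmr_ivw(h) -> MREstimate:
    if h.k == 1:
        return wald_ratio(h.beta_x[0], h.se_x[0], h.beta_y[0], h.se_y[0])
    return ivw(h)


def run_two_step(exposure: SummaryStats, mediator: SummaryStats,
                 outcome: SummaryStats,
                 config: TwoStepConfig | None = None) -> TwoStepResult:
    """Full two-step mediation analysis for one (exposure, mediator, outcome).

    Stage failures raise :class:`InsufficientInstrumentsError` with the
    stage named.
    """
    cfg = config or TwoStepConfig()
    logs: dict[str, dict[str, int]] = {}
    sens: dict[str, SensitivityReport] = {}

    def _stage(name, fn):
        try:
            return fn()
        except InsufficientInstrumentsError as exc:
            raise InsufficientInstrumentsError(f"[{name}] {exc}") from exc

    def _pair(exp, out, label):
        h, log = build_harmonized(
            exp, out, p_threshold=cfg.p_threshold, ld=cfg.ld, r2_max=cfg.r2_max,
            window_kb=cfg.window_kb, f_min=cfg.f_min, exclude=cfg.exclude,
        )
        logs[label] = log
        if cfg.run_sensitivity and h.k >= 4:
            report, h = run_sensitivity(h, n_sim=cfg.presso_sims, seed=cfg.seed)
            sens[label] = report
        return h

    h_total = _stage("exposure->outcome", lambda: _pair(exposure, outcome, "total"))
    total = _uvmr_ivw(h_total)
    h_xz = _stage("exposure->mediator", lambda: _pair(exposure, mediator, "xz"))
    xz = _uvmr_ivw(h_xz)

    def _mv():
        inst_x = drop_weak_instruments(
            clump(select_by_pvalue(exposure, cfg.p_threshold), cfg.ld,
                  r2_max=cfg.r2_max, window_kb=cfg.window_kb), cfg.f_min)
        inst_z = drop_weak_instruments(
            clump(select_by_pvalue(mediator, cfg.p_threshold), cfg.ld,
                  r2_max=cfg.r2_max, window_kb=cfg.window_kb), cfg.f_min)
        mv = mvmr_harmonize({exposure.trait_name: inst_x,
                             mediator.trait_name: inst_z},
                            [exposure, mediator], outcome, ld=cfg.ld,
                            r2_max=cfg.r2_max, window_kb=cfg.window_kb)
        if cfg.exclude:
            keep = ~np.isin(mv.variant_id.astype(str), list(cfg.exclude))
            mv = MVHarmonizedSet(mv.outcome_name, mv.exposure_names,
                                 mv.variant_id[keep], mv.beta_x[keep],
                                 mv.se_x[keep], mv.beta_y[keep], mv.se_y[keep])
        return mv

    mv = _stage("mvmr", _mv)
    mv_res = mvmr_ivw(mv)
    zy = mv_res.estimates[mediator.trait_name]
    mediation = mediation_decompose(total.beta, xz.beta, zy.beta)
    return TwoStepResult(mediation, total, xz, zy, mv_res, sens, logs)
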