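"""Heterogeneity, pleiotropy, outlier and influence diagnostics.

These diagnostics gate which causal claims stand: Cochran's Q for
heterogeneity among per-SNP ratio estimates, the MR-Egger intercept and
the MR-PRESSO global test for horizontal pleiotropy, MR-PRESSO per-SNP
outlier detection with a remove-and-rerun loop, and leave-one-out
influence analysis.  ``sensitivity_gate`` applies the decision rule: a
relationship is called positive only when IVW is significant, all
methods agree in direction, and no uncorrected pleiotropy remains;
heterogeneity alone switches the IVW to multiplicative random effects
rather than invalidating the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .estimators import MREstimate, _ivw_fixed, egger, ivw, p_from_z
from .instruments import HarmonizedSet, InsufficientInstrumentsError


@dataclass
class LooEstimate:
    left_out: str
    beta: float
    se: float
    pvalue: float


@dataclass
class PressoResult:
    global_rss: float
    global_p: float
    outliers: set[str]
    outlier_pvalues: dict[str, float]
    distortion_p: float | None


@dataclass
class SensitivityReport:
    """Collected diagnostics for one harmonized exposure/outcome pair."""

    q_value: float | None = None
    q_df: int | None = None
    q_pvalue: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    presso_global_p: float | None = None
    presso_outliers: set[str] = field(default_factory=set)
    presso_distortion_p: float | None = None
    loo_estimates: list[LooEstimate] = field(default_factory=list)
    loo_flagged: set[str] = field(default_factory=set)
    robust: bool | None = None


def cochran_q(h: HarmonizedSet) -> tuple[float, int, float]:
    """Cochran's Q over per-SNP ratio estimates.

    Q = Σ w_j (θ_j − θ_IVW)² with w_j = β_xj²/se_yj² (the first-order
    inverse ratio variance), which equals the weighted residual sum of
    squares of the fixed-effect IVW regression through the origin.
    p is the chi-square upper tail on k−1 df.
    """
    if h.k < 2:
        raise InsufficientInstrumentsError("cochran_q requires k >= 2")
    _, _, q = _ivw_fixed(h)
    df = h.k - 1
    return float(q), df, float(sps.chi2.sf(q, df))


def egger_intercept_test(h: HarmonizedSet) -> tuple[float, float, float]:
    """Egger intercept, SE and two-sided p (shared code path with egger)."""
    e = egger(h)
    return e.extra["intercept"], e.extra["intercept_se"], e.extra["intercept_p"]


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes via sum updates (vectorized over SNPs)."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx * bx)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def mr_presso(h: HarmonizedSet, n_sim: int = 1000, outlier_alpha: float = 0.05,
              seed: int = 0) -> PressoResult:
    """MR-PRESSO global pleiotropy test and per-SNP outlier detection.

    The observed statistic is RSS_obs = Σ_j w_j (β_yj − θ_(−j) β_xj)²
    with θ_(−j) the leave-one-out IVW slope and w_j = 1/se_yj².  The
    null is built from ``n_sim`` parametric draws
    β*_xj ~ N(β_xj, se_xj²), β*_yj ~ N(θ_(−j) β_xj, se_yj²), with the
    LOO slopes recomputed inside each draw.  Monte-Carlo p-values use
    the (1 + #exceedances)/(n_sim + 1) correction.  Per-SNP outliers are
    Bonferroni-flagged at ``outlier_alpha``/k; when outliers are found,
    the distortion p compares the observed change in the IVW slope after
    their removal against removals of random same-sized subsets.
    """
    if h.k < 4:
        raise InsufficientInstrumentsError("mr_presso requires k >= 4")
    rng = np.random.default_rng(seed)
    k = h.k
    w = 1.0 / h.se_y**2

    loo = _loo_slopes(h.beta_x, h.beta_y, w)
    res_obs = w * (h.beta_y - loo * h.beta_x) ** 2
    rss_obs = float(np.sum(res_obs))

    bx_sim = rng.normal(h.beta_x, h.se_x, size=(n_sim, k))
    by_sim = rng.normal(loo * h.beta_x, h.se_y, size=(n_sim, k))
    w_row = w[None, :]
    sxy = np.sum(w_row * bx_sim * by_sim, axis=1, keepdims=True)
    sxx = np.sum(w_row * bx_sim**2, axis=1, keepdims=True)
    loo_sim = (sxy - w_row * bx_sim * by_sim) / (sxx - w_row * bx_sim**2)
    res_sim = w_row * (by_sim - loo_sim * bx_sim) ** 2
    rss_sim = res_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    p_snp = (1 + np.sum(res_sim >= res_obs[None, :], axis=0)) / (n_sim + 1)
    flagged = p_snp < outlier_alpha / k
    outliers = set(h.variant_id[flagged])
    outlier_pvalues = dict(zip(h.variant_id, map(float, p_snp)))

    distortion_p = None
    n_out = int(np.sum(flagged))
    if 0 < n_out < k - 1:
        slope_all, _, _ = _ivw_fixed(h)
        slope_clean, _, _ = _ivw_fixed(h.subset(~flagged))
        if slope_clean != 0:
            d_obs = abs((slope_all - slope_clean) / slope_clean)
            d_null = np.empty(n_sim)
            for s in range(n_sim):
                drop = rng.choice(k, size=n_out, replace=False)
                mask = np.ones(k, dtype=bool)
                mask[drop] = False
                slope_s, _, _ = _ivw_fixed(h.subset(mask))
                d_null[s] = abs((slope_all - slope_s) / slope_s) if slope_s != 0 else np.inf
            distortion_p = float((1 + np.sum(d_null >= d_obs)) / (n_sim + 1))
    return PressoResult(rss_obs, global_p, outliers, outlier_pvalues, distortion_p)


def leave_one_out(h: HarmonizedSet) -> tuple[list[LooEstimate], set[str]]:
    """Fixed-effect IVW with each SNP left out in turn.

    Flags any SNP whose omission flips the sign of the estimate or its
    significance at 0.05 relative to the full-set IVW.
    """
    if h.k < 3:
        raise InsufficientInstrumentsError("leave_one_out requires k >= 3")
    w = 1.0 / h.se_y**2
    slopes = _loo_slopes(h.beta_x, h.beta_y, w)
    sxx = np.sum(w * h.beta_x**2)
    ses = np.sqrt(1.0 / (sxx - w * h.beta_x**2))
    full_slope, full_se, _ = _ivw_fixed(h)
    full_sig = p_from_z(full_slope, full_se) < 0.05
    estimates, flagged = [], set()
    for j in range(h.k):
        p = p_from_z(slopes[j], ses[j])
        estimates.append(LooEstimate(str(h.variant_id[j]), float(slopes[j]),
                                     float(ses[j]), p))
        if np.sign(slopes[j]) != np.sign(full_slope) or (p < 0.05) != full_sig:
            flagged.add(str(h.variant_id[j]))
    return estimates, flagged


def run_sensitivity(h: HarmonizedSet, n_sim: int = 1000, seed: int = 0,
                    outlier_alpha: float = 0.05,
                    max_rounds: int = 1) -> tuple[SensitivityReport, HarmonizedSet]:
    """Full diagnostic suite with MR-PRESSO remove-and-rerun.

    Outlier removal runs for up to ``max_rounds`` rounds (default a
    single remove-and-rerun); Q, the Egger intercept, the final global
    test and leave-one-out are reported on the outlier-corrected set.
    Returns the report and the (possibly reduced) harmonized set.
    """
    report = SensitivityReport()
    current = h
    removed: set[str] = set()
    if current.k >= 4:
        for round_i in range(max(1, max_rounds)):
            presso = mr_presso(current, n_sim=n_sim, outlier_alpha=outlier_alpha,
                               seed=seed + round_i)
            report.presso_global_p = presso.global_p
            report.presso_distortion_p = presso.distortion_p
            if not presso.outliers:
                break
            removed |= presso.outliers
            reduced = current.drop_ids(presso.outliers)
            if reduced.k < 4:
                current = reduced
                break
            current = reduced
        else:
            round_i = max_rounds
        if removed and current.k >= 4:
            # post-removal global test is what the gate consults
            presso_final = mr_presso(current, n_sim=n_sim,
                                     outlier_alpha=outlier_alpha,
                                     seed=seed + 101)
            report.presso_global_p = presso_final.global_p
    report.presso_outliers = removed

    if current.k >= 2:
        q, q_df, q_p = cochran_q(current)
        report.q_value, report.q_df, report.q_pvalue = q, q_df, q_p
    if current.k >= 3:
        itc, itc_se, itc_p = egger_intercept_test(current)
        report.egger_intercept = itc
        report.egger_intercept_se = itc_se
        report.egger_intercept_p = itc_p
        loo, loo_flagged = leave_one_out(current)
        report.loo_estimates = loo
        report.loo_flagged = loo_flagged
    return report, current


def sensitivity_gate(estimates: list[MREstimate],
                     report: SensitivityReport) -> tuple[bool, str, str]:
    """Decision rule for calling a causal relationship positive.

    Positive requires: IVW p < 0.05; all method betas share sign; Egger
    intercept p >= 0.05 (when computable); MR-PRESSO global p >= 0.05
    after any outlier-removal rerun.  Significant heterogeneity only
    switches the IVW model to multiplicative random effects.  Returns
    (robust, verdict, note) where verdict names the failing condition.
    """
    ivw_est = next((e for e in estimates if e.method in ("ivw", "wald_ratio")), None)
    if ivw_est is None:
        raise ValueError("gate requires an IVW (or Wald-ratio) estimate")
    model_note = ivw_est.model_note
    if report.q_pvalue is not None and report.q_pvalue < 0.05:
        model_note = "multiplicative_random_effects"
    if ivw_est.pvalue >= 0.05:
        return False, "not_established", "ivw_not_significant"
    signs = {np.sign(e.beta) for e in estimates}
    if len(signs) > 1 or 0.0 in signs:
        return False, "not_established", "inconsistent_directions"
    if report.egger_intercept_p is not None and report.egger_intercept_p < 0.05:
        return False, "not_established", "pleiotropy_egger_intercept"
    if report.presso_global_p is not None and report.presso_global_p < 0.05:
        return False, "not_established", "pleiotropy_presso_global"
    return True, "positive", model_note
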