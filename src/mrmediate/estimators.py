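"""Univariable two-sample MR estimators.

Five estimators operate on a :class:`~mrmediate.instruments.HarmonizedSet`
of per-SNP exposure/outcome effect pairs (beta_xj, beta_yj):

* Wald ratio — single-SNP estimate beta_yj / beta_xj.
* IVW — weighted regression of SNP-outcome on SNP-exposure effects
  through the origin, weights 1/se_yj²; fixed-effect by default, with a
  multiplicative random-effects variance inflation max(1, sqrt(Q/(k−1)))
  applied automatically when Cochran's Q is significant at 0.05.
* MR-Egger — the same regression with an intercept after orienting every
  SNP to a non-negative exposure effect; a non-zero intercept indicates
  directional horizontal pleiotropy.
* Weighted median — consistent when instruments carrying at least half
  the weight are valid.
* Simple / weighted mode — kernel-density mode of the per-SNP ratio
  estimates; consistent when the largest homogeneous cluster is valid.

Estimates for binary outcomes are log odds ratios; ``beta_to_or``
converts to the OR scale with a 1.96-SE 95% interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .instruments import HarmonizedSet, InsufficientInstrumentsError

Z95 = 1.96

METHODS = ("wald_ratio", "ivw", "egger", "weighted_median", "weighted_mode", "simple_mode")


@dataclass
class MREstimate:
    """One method's causal estimate with OR-scale display fields."""

    method: str
    beta: float
    se: float
    pvalue: float
    or_value: float
    ci_low: float
    ci_high: float
    k: int
    model_note: str = "not_applicable"
    extra: dict = field(default_factory=dict)


def p_from_z(beta: float, se: float) -> float:
    """Two-sided normal p-value, p = 2·Φ(−|beta/se|), floored at 1e-300."""
    if se <= 0:
        raise ValueError("se must be positive")
    return float(min(max(2.0 * sps.norm.sf(abs(beta / se)), 1e-300), 1.0))


def beta_to_or(beta: float, se: float) -> tuple[float, float, float]:
    """Odds ratio and 95% CI, (exp(β), exp(β − 1.96·se), exp(β + 1.96·se))."""
    if se < 0:
        raise ValueError("se must be non-negative")
    return (float(np.exp(beta)),
            float(np.exp(beta - Z95 * se)),
            float(np.exp(beta + Z95 * se)))


def se_from_ci(low: float, high: float) -> float:
    """Standard error recovered from a 95% interval: (high − low)/(2·1.96)."""
    if high <= low:
        raise ValueError("need high > low")
    return (high - low) / (2.0 * Z95)


def _make_estimate(method: str, beta: float, se: float, k: int,
                   model_note: str = "not_applicable",
                   extra: dict | None = None) -> MREstimate:
    or_value, ci_low, ci_high = beta_to_or(beta, se)
    return MREstimate(method=method, beta=float(beta), se=float(se),
                      pvalue=p_from_z(beta, se), or_value=or_value,
                      ci_low=ci_low, ci_high=ci_high, k=int(k),
                      model_note=model_note, extra=extra or {})


def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float) -> MREstimate:
    """Single-SNP causal estimate beta_y/beta_x with first-order SE se_y/|beta_x|."""
    if beta_x == 0:
        raise ValueError("wald_ratio undefined for beta_x = 0")
    return _make_estimate("wald_ratio", beta_y / beta_x, se_y / abs(beta_x), k=1)


def _ivw_fixed(h: HarmonizedSet) -> tuple[float, float, float]:
    """Fixed-effect IVW slope, SE and Cochran's Q (regression through origin)."""
    w = 1.0 / h.se_y**2
    sxx = float(np.sum(w * h.beta_x**2))
    slope = float(np.sum(w * h.beta_x * h.beta_y)) / sxx
    se = float(np.sqrt(1.0 / sxx))
    q = float(np.sum(w * (h.beta_y - slope * h.beta_x) ** 2))
    return slope, se, q


def ivw(h: HarmonizedSet, model: str = "auto") -> MREstimate:
    """Inverse-variance-weighted estimate.

    ``model`` is ``'fixed'``, ``'multiplicative_random_effects'`` or
    ``'auto'`` (fixed unless Cochran's Q has p < 0.05, mirroring common
    practice of reporting heterogeneous results under random effects).
    """
    if h.k < 2:
        raise InsufficientInstrumentsError("ivw requires k >= 2; use wald_ratio")
    slope, se_fixed, q = _ivw_fixed(h)
    q_p = float(sps.chi2.sf(q, h.k - 1))
    if model == "auto":
        model = "multiplicative_random_effects" if q_p < 0.05 else "fixed"
    if model == "fixed":
        se = se_fixed
    elif model == "multiplicative_random_effects":
        se = se_fixed * max(1.0, float(np.sqrt(q / (h.k - 1))))
    else:
        raise ValueError(f"unknown IVW model {model!r}")
    return _make_estimate("ivw", slope, se, h.k, model_note=model,
                          extra={"q_value": q, "q_pvalue": q_p})


def _oriented(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    """Exposure/outcome betas with every SNP flipped to beta_x >= 0."""
    sign = np.where(h.beta_x < 0, -1.0, 1.0)
    return sign * h.beta_x, sign * h.beta_y


def egger(h: HarmonizedSet) -> MREstimate:
    """MR-Egger regression: weighted fit of beta_y on beta_x with intercept.

    SNPs are first oriented to non-negative exposure effects.  Slope and
    intercept SEs carry a multiplicative overdispersion factor
    max(1, sqrt(RSS/(k−2))).
    """
    if h.k < 3:
        raise InsufficientInstrumentsError("egger requires k >= 3")
    bx, by = _oriented(h)
    w = 1.0 / h.se_y**2
    X = np.column_stack([np.ones_like(bx), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - X @ coef
    rss = float(np.sum(w * resid**2))
    phi = max(1.0, rss / (h.k - 2))
    cov = phi * np.linalg.inv(xtwx)
    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    return _make_estimate(
        "egger", slope, se_slope, h.k,
        extra={
            "intercept": intercept,
            "intercept_se": se_int,
            "intercept_p": p_from_z(intercept, se_int),
            "rss": rss,
        },
    )


def _ratio_estimates(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Wald ratios and their first-order SEs."""
    theta = h.beta_y / h.beta_x
    se_theta = h.se_y / np.abs(h.beta_x)
    return theta, se_theta


def _weighted_median_value(theta: np.ndarray, w: np.ndarray) -> float:
    """Weighted median by linear interpolation at cumulative weight 0.5.

    Percentile positions follow p_j = (Σ_{i≤j} w_i − w_j/2) / Σw.
    """
    order = np.argsort(theta, kind="stable")
    th, ww = theta[order], w[order]
    ww = ww / ww.sum()
    cum = np.cumsum(ww) - ww / 2.0
    return float(np.interp(0.5, cum, th))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE (seeded)."""
    if h.k < 3:
        raise InsufficientInstrumentsError("weighted_median requires k >= 3")
    theta, se_theta = _ratio_estimates(h)
    w = 1.0 / se_theta**2
    est = _weighted_median_value(theta, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    bx = rng.normal(h.beta_x, h.se_x, size=(n_boot, h.k))
    by = rng.normal(h.beta_y, h.se_y, size=(n_boot, h.k))
    for b in range(n_boot):
        th_b = by[b] / bx[b]
        w_b = bx[b] ** 2 / h.se_y**2
        boots[b] = _weighted_median_value(th_b, w_b)
    se = float(np.std(boots, ddof=1))
    return _make_estimate("weighted_median", est, se, h.k)


def _mode_value(theta: np.ndarray, w: np.ndarray, bandwidth_factor: float) -> float:
    """Kernel-density mode of ratio estimates with normal-reference bandwidth."""
    k = len(theta)
    s = float(np.std(theta, ddof=1)) if k > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(theta, [75, 25])))
    spread = min(s, iqr / 1.349) if iqr > 0 else s
    h_bw = bandwidth_factor * 0.9 * spread * k ** (-0.2)
    if h_bw <= 0:
        return float(theta[0])
    grid = np.linspace(theta.min() - 3 * h_bw, theta.max() + 3 * h_bw, 2048)
    dens = (w[:, None] * np.exp(-0.5 * ((grid[None, :] - theta[:, None]) / h_bw) ** 2)).sum(axis=0)
    return float(grid[np.argmax(dens)])


def mode_estimators(h: HarmonizedSet, variant: str = "weighted",
                    bandwidth_factor: float = 1.0, n_boot: int = 1000,
                    seed: int = 0) -> MREstimate:
    """Simple or weighted mode-based estimator, bootstrap SE (seeded)."""
    if h.k < 3:
        raise InsufficientInstrumentsError("mode estimators require k >= 3")
    if variant not in ("simple", "weighted"):
        raise ValueError(f"variant must be 'simple' or 'weighted', got {variant!r}")
    theta, se_theta = _ratio_estimates(h)
    weights = 1.0 / se_theta**2 if variant == "weighted" else np.ones_like(theta)
    est = _mode_value(theta, weights, bandwidth_factor)
    rng = np.random.default_rng(seed)
    bx = rng.normal(h.beta_x, h.se_x, size=(n_boot, h.k))
    by = rng.normal(h.beta_y, h.se_y, size=(n_boot, h.k))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        th_b = by[b] / bx[b]
        w_b = bx[b] ** 2 / h.se_y**2 if variant == "weighted" else np.ones(h.k)
        boots[b] = _mode_value(th_b, w_b, bandwidth_factor)
    se = float(np.std(boots, ddof=1))
    return _make_estimate(f"{variant}_mode", est, se, h.k)


def run_all_methods(h: HarmonizedSet, seed: int = 0,
                    n_boot: int = 1000) -> list[MREstimate]:
    """All applicable estimators for one harmonized set, in a fixed order.

    A single instrument yields only the Wald ratio; two instruments IVW
    only; three or more run the full five-method suite.
    """
    if h.k == 1:
        return [wald_ratio(h.beta_x[0], h.se_x[0], h.beta_y[0], h.se_y[0])]
    out = [ivw(h)]
    if h.k >= 3:
        out.append(egger(h))
        out.append(weighted_median(h, n_boot=n_boot, seed=seed))
        out.append(mode_estimators(h, "weighted", n_boot=n_boot, seed=seed + 1))
        out.append(mode_estimators(h, "simple", n_boot=n_boot, seed=seed + 2))
    return out


def direction_consistent(estimates: Sequence[MREstimate]) -> bool:
    """True when every method's beta shares the same strict sign."""
    signs = {np.sign(e.beta) for e in estimates}
    return len(signs) == 1 and 0.0 not in signs
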