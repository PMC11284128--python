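"""Cross-cohort meta-analysis and grouped false-discovery-rate control.

``meta_combine`` pools per-cohort causal estimates by inverse-variance
weighting — fixed-effect by default, or DerSimonian–Laird random
effects — and reports Cochran's Q and I² for between-cohort
heterogeneity.  ``bh_adjust`` applies the Benjamini–Hochberg step-up
within user-defined test families (e.g. per taxonomic rank and
outcome), and ``classify_association`` applies the two-tier call:
significant when P < 0.05 and P_FDR < 0.1, potential when P < 0.05 but
P_FDR >= 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .estimators import Z95, p_from_z


@dataclass
class MetaResult:
    pooled_beta: float
    pooled_se: float
    pooled_p: float
    or_value: float
    ci_low: float
    ci_high: float
    q_value: float
    q_pvalue: float
    i_squared: float
    model: str
    tau2: float = 0.0
    n_studies: int = 0


@dataclass
class AssociationCall:
    p: float
    p_fdr: float
    group_label: str
    call: str  # significant | potential | none


def meta_combine(estimates: Sequence[tuple[float, float]],
                 model: str = "fixed") -> MetaResult:
    """Pool (beta, se) estimates across cohorts.

    Fixed effect uses weights 1/se²; DerSimonian–Laird adds the moment
    estimate tau² = max(0, (Q − (n−1)) / (Σw − Σw²/Σw)) to every
    variance.  I² = max(0, (Q − df)/Q)·100 is computed from the
    fixed-effect Q in either model.  A single estimate passes through
    with model ``not_applicable``.
    """
    if model not in ("fixed", "dersimonian_laird"):
        raise ValueError(f"unknown meta model {model!r}")
    beta = np.array([b for b, _ in estimates], dtype=float)
    se = np.array([s for _, s in estimates], dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    n = len(beta)
    if n == 0:
        raise ValueError("meta_combine needs at least one estimate")
    if n == 1:
        b, s = float(beta[0]), float(se[0])
        return MetaResult(b, s, p_from_z(b, s), float(np.exp(b)),
                          float(np.exp(b - Z95 * s)), float(np.exp(b + Z95 * s)),
                          0.0, 1.0, 0.0, "not_applicable", 0.0, 1)

    w = 1.0 / se**2
    pooled_fixed = float(np.sum(w * beta) / np.sum(w))
    q = float(np.sum(w * (beta - pooled_fixed) ** 2))
    df = n - 1
    q_p = float(sps.chi2.sf(q, df))
    i2 = float(max(0.0, (q - df) / q) * 100.0) if q > 0 else 0.0

    tau2 = 0.0
    if model == "fixed":
        pooled = pooled_fixed
        pooled_se = float(np.sqrt(1.0 / np.sum(w)))
    else:
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = float(max(0.0, (q - df) / denom)) if denom > 0 else 0.0
        w_dl = 1.0 / (se**2 + tau2)
        pooled = float(np.sum(w_dl * beta) / np.sum(w_dl))
        pooled_se = float(np.sqrt(1.0 / np.sum(w_dl)))
    return MetaResult(pooled, pooled_se, p_from_z(pooled, pooled_se),
                      float(np.exp(pooled)), float(np.exp(pooled - Z95 * pooled_se)),
                      float(np.exp(pooled + Z95 * pooled_se)),
                      q, q_p, i2, model, tau2, n)


def bh_adjust(pvalues: Sequence[float],
              groups: Sequence[str] | None = None) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values, computed within each group.

    Results are returned in input order; with ``groups`` omitted all
    p-values form a single family.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0,1]")
    if groups is None:
        groups = ["all"] * len(p)
    if len(groups) != len(p):
        raise ValueError("groups must parallel pvalues")
    out = np.empty_like(p)
    labels = np.asarray(groups, dtype=object)
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        out[idx] = multipletests(p[idx], method="fdr_bh")[1]
    return out


def classify_association(p: float, p_fdr: float,
                         group_label: str = "") -> AssociationCall:
    """Two-tier association call from raw and FDR-adjusted p-values."""
    if p < 0.05 and p_fdr < 0.1:
        call = "significant"
    elif p < 0.05:
        call = "potential"
    else:
        call = "none"
    return AssociationCall(float(p), float(p_fdr), group_label, call)
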