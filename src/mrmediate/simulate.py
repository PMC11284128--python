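"""Synthetic GWAS summary statistics under a known causal chain.

The generator emulates the three-cornered summary-data design this
package analyses: an exposure X (e.g. a microbial taxon's abundance), a
mediator Z (a circulating protein) and a binary outcome Y (a disease,
on the log-odds scale), linked by the chain

    X --gamma--> Z --delta--> Y,   plus a direct effect X --tau--> Y,

so the true total effect of X on Y is tau + gamma*delta and the true
mediated proportion is gamma*delta / (tau + gamma*delta).

Per SNP j with minor-allele frequency p_j, the true per-allele exposure
effect b_j is drawn Normal(0, exposure_effect_sd²); sampling standard
errors follow the standardized-trait form se = 1/sqrt(2 p_j (1−p_j) N)
for each GWAS's sample size N, and observed effects are the true
effects plus Normal(0, se²) noise — the three GWAS are sampled
independently (non-overlapping cohorts).  The mediator additionally
carries its own instruments (SNPs with no exposure effect), without
which the exposure and mediator columns of a multivariable design would
be collinear and the mediator's direct effect unidentifiable.

Invalid instruments receive a direct SNP→outcome (pleiotropic) effect
alpha_j ~ Normal(pleiotropy_mean, pleiotropy_sd²) applied relative to
the exposure-increasing allele, i.e. the outcome effect gains
sign(b_j)·alpha_j; this is what "directional" pleiotropy means here,
and it is what the MR-Egger intercept estimates after its beta_x >= 0
orientation.  Planted gross outliers shift the observed outcome beta by
±10 standard errors.  Identical seeds give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sumstats import LDTable, SummaryStats

_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                   ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")]


class SimConfigError(ValueError):
    """Raised for degenerate simulation configurations."""


@dataclass
class ChainSimConfig:
    """Parameters of the synthetic exposure→mediator→outcome chain.

    Defaults describe the chain used throughout the package's recovery
    tests: gamma = 0.3, delta = −0.5, tau = −0.2 (mediated proportion
    42.9%), 100 exposure instruments and 100 mediator-specific
    instruments, exposure/mediator GWAS of 10⁶ and a 2×10⁵ outcome GWAS
    so that instruments are strong and exposure-side sampling error is
    negligible next to the outcome-side error.
    """

    n_snps: int = 100
    n_mediator_snps: int = 100
    n_exposure: int = 1_000_000
    n_mediator: int = 1_000_000
    n_outcome: int = 200_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    exposure_effect_sd: float = 0.1
    mediator_effect_sd: float = 0.1
    theta_xz: float = 0.3
    theta_zy: float = -0.5
    theta_direct: float = -0.2
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    prop_invalid: float = 0.0
    n_outliers: int = 0
    palindrome_frac: float = 0.0
    ld_block_size: int = 1
    ld_block_r2: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 3:
            raise SimConfigError(f"n_snps must be >= 3, got {self.n_snps}")
        if not 0.0 <= self.prop_invalid <= 1.0:
            raise SimConfigError("prop_invalid must lie in [0,1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise SimConfigError("maf_range must lie within (0, 0.5]")
        if self.n_mediator_snps < 0 or self.n_outliers < 0:
            raise SimConfigError("counts must be non-negative")
        if self.ld_block_size < 1:
            raise SimConfigError("ld_block_size must be >= 1")


@dataclass
class SimTruth:
    """Ground truth of one simulated chain, for recovery tests."""

    theta_xz: float
    theta_zy: float
    theta_direct: float
    beta_total_true: float
    pleiotropic_ids: set[str] = field(default_factory=set)
    outlier_ids: set[str] = field(default_factory=set)
    per_snp_exposure_effects: dict[str, float] = field(default_factory=dict)
    mediator_snp_ids: set[str] = field(default_factory=set)

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        for key in ("pleiotropic_ids", "outlier_ids", "mediator_snp_ids"):
            d[key] = sorted(d[key])
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        for key in ("pleiotropic_ids", "outlier_ids", "mediator_snp_ids"):
            d[key] = set(d[key])
        return cls(**d)


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy import stats as sps

    p = 2.0 * sps.norm.sf(np.abs(beta / se))
    return np.clip(p, 1e-300, 1.0)


@dataclass
class _ChainDraw:
    """Deterministic latent state shared by all GWAS of one chain."""

    ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ea: np.ndarray
    oa: np.ndarray
    maf: np.ndarray
    b: np.ndarray           # true exposure effects (0 for mediator-specific SNPs)
    m: np.ndarray           # mediator-specific effects (0 for exposure SNPs)
    alpha: np.ndarray       # oriented pleiotropic outcome effects
    invalid: np.ndarray
    outlier: np.ndarray


def _draw_chain(cfg: ChainSimConfig, rng: np.random.Generator) -> _ChainDraw:
    n_total = cfg.n_snps + cfg.n_mediator_snps
    ids = np.array([f"rs{i + 1}" for i in range(n_total)], dtype=object)

    if cfg.ld_block_size > 1:
        n_blocks = int(np.ceil(n_total / cfg.ld_block_size))
        block = np.repeat(np.arange(n_blocks), cfg.ld_block_size)[:n_total]
        within = np.concatenate([np.arange(np.sum(block == g)) for g in range(n_blocks)])
        chrom = (block % 22 + 1).astype(str)
        pos = 1_000_000 + (block // 22) * 50_000_000 + within * 1_000
    else:
        chrom = (np.arange(n_total) % 22 + 1).astype(str)
        pos = 1_000_000 + (np.arange(n_total) // 22) * 50_000_000
    chrom = chrom.astype(object)
    pos = pos.astype(np.int64)

    n_pal = int(round(cfg.palindrome_frac * n_total))
    pal_idx = rng.choice(n_total, size=n_pal, replace=False) if n_pal else np.array([], int)
    pair_choice = rng.integers(0, 8, size=n_total)
    ea = np.array([_NONPALINDROMIC[c][0] for c in pair_choice], dtype=object)
    oa = np.array([_NONPALINDROMIC[c][1] for c in pair_choice], dtype=object)
    pal_pairs = rng.integers(0, 4, size=n_pal)
    for i, j in enumerate(pal_idx):
        ea[j], oa[j] = _PALINDROMIC[pal_pairs[i]]

    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=n_total)

    b = np.zeros(n_total)
    b[: cfg.n_snps] = rng.normal(0.0, cfg.exposure_effect_sd, size=cfg.n_snps)
    m = np.zeros(n_total)
    if cfg.n_mediator_snps:
        m[cfg.n_snps:] = rng.normal(0.0, cfg.mediator_effect_sd, size=cfg.n_mediator_snps)

    invalid = np.zeros(n_total, dtype=bool)
    n_invalid = int(round(cfg.prop_invalid * cfg.n_snps))
    if n_invalid:
        invalid[rng.choice(cfg.n_snps, size=n_invalid, replace=False)] = True
    alpha = np.zeros(n_total)
    if n_invalid:
        raw = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=n_invalid)
        # directional pleiotropy is defined on the exposure-increasing allele
        alpha[invalid] = np.sign(b[invalid]) * raw

    outlier = np.zeros(n_total, dtype=bool)
    if cfg.n_outliers:
        outlier[rng.choice(cfg.n_snps, size=cfg.n_outliers, replace=False)] = True

    return _ChainDraw(ids, chrom, pos, ea, oa, maf, b, m, alpha, invalid, outlier)


def _gwas_from_truth(draw: _ChainDraw, true_beta: np.ndarray, n: int,
                     trait_name: str, trait_type: str,
                     rng: np.random.Generator,
                     outlier_shift: np.ndarray | None = None) -> SummaryStats:
    se = 1.0 / np.sqrt(2.0 * draw.maf * (1.0 - draw.maf) * n)
    beta_obs = rng.normal(true_beta, se)
    if outlier_shift is not None:
        beta_obs = beta_obs + outlier_shift * se
    df = pd.DataFrame({
        "variant_id": draw.ids,
        "chrom": draw.chrom,
        "pos": draw.pos,
        "effect_allele": draw.ea,
        "other_allele": draw.oa,
        "eaf": draw.maf,
        "beta": beta_obs,
        "se": se,
        "pvalue": _two_sided_p(beta_obs, se),
        "n": np.full(len(draw.ids), n, dtype=np.int64),
    })
    return SummaryStats(trait_name, trait_type, df)


def simulate_chain(
    cfg: ChainSimConfig,
) -> tuple[SummaryStats, SummaryStats, SummaryStats, SimTruth]:
    """Generate (exposure, mediator, outcome, truth) for one chain."""
    rng = np.random.default_rng(cfg.seed)
    draw = _draw_chain(cfg, rng)

    true_x = draw.b
    true_z = cfg.theta_xz * draw.b + draw.m
    beta_total = cfg.theta_direct + cfg.theta_xz * cfg.theta_zy
    true_y = beta_total * draw.b + cfg.theta_zy * draw.m + draw.alpha

    exposure = _gwas_from_truth(draw, true_x, cfg.n_exposure, "exposure",
                                "continuous", rng)
    mediator = _gwas_from_truth(draw, true_z, cfg.n_mediator, "mediator",
                                "continuous", rng)
    shift = np.where(draw.outlier, rng.choice([-10.0, 10.0], size=len(draw.ids)), 0.0)
    outcome = _gwas_from_truth(draw, true_y, cfg.n_outcome, "outcome",
                               "binary", rng, outlier_shift=shift)

    truth = SimTruth(
        theta_xz=cfg.theta_xz,
        theta_zy=cfg.theta_zy,
        theta_direct=cfg.theta_direct,
        beta_total_true=beta_total,
        pleiotropic_ids=set(draw.ids[draw.invalid]),
        outlier_ids=set(draw.ids[draw.outlier]),
        per_snp_exposure_effects=dict(zip(draw.ids, map(float, draw.b))),
        mediator_snp_ids=set(draw.ids[cfg.n_snps:]),
    )
    return exposure, mediator, outcome, truth


def simulate_cohort_pair(
    cfg: ChainSimConfig, n_outcome_2: int, seed_2: int,
    truth_offset: float = 0.0,
) -> tuple[SummaryStats, SummaryStats]:
    """Two outcome GWAS sharing one chain's true effects.

    Cohort A is the outcome of ``simulate_chain(cfg)``; cohort B redraws
    only the sampling noise with its own seed and sample size.
    ``truth_offset`` shifts cohort B's true per-SNP effects by
    offset × b_j, for exercising between-cohort heterogeneity tests.
    """
    # replay simulate_chain's stream so cohort A matches its outcome draw
    rng = np.random.default_rng(cfg.seed)
    draw = _draw_chain(cfg, rng)
    beta_total = cfg.theta_direct + cfg.theta_xz * cfg.theta_zy
    true_y = beta_total * draw.b + cfg.theta_zy * draw.m + draw.alpha
    _ = _gwas_from_truth(draw, draw.b, cfg.n_exposure, "exposure", "continuous", rng)
    _ = _gwas_from_truth(draw, cfg.theta_xz * draw.b + draw.m, cfg.n_mediator,
                         "mediator", "continuous", rng)
    shift = np.where(draw.outlier, rng.choice([-10.0, 10.0], size=len(draw.ids)), 0.0)
    outcome_a = _gwas_from_truth(draw, true_y, cfg.n_outcome, "outcome_A",
                                 "binary", rng, outlier_shift=shift)

    rng_b = np.random.default_rng(seed_2)
    true_y_b = true_y + truth_offset * draw.b
    outcome_b = _gwas_from_truth(draw, true_y_b, n_outcome_2, "outcome_B",
                                 "binary", rng_b, outlier_shift=shift)
    return outcome_a, outcome_b


def block_ld_table(cfg: ChainSimConfig) -> LDTable:
    """LD table matching the configured block structure.

    SNPs in the same block share pairwise r² = ``ld_block_r2``; SNPs in
    different blocks are absent from the table (r² treated as 0).
    """
    table = LDTable()
    if cfg.ld_block_size <= 1 or cfg.ld_block_r2 <= 0:
        return table
    n_total = cfg.n_snps + cfg.n_mediator_snps
    ids = [f"rs{i + 1}" for i in range(n_total)]
    for start in range(0, n_total, cfg.ld_block_size):
        members = ids[start:start + cfg.ld_block_size]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                table.set(members[i], members[j], cfg.ld_block_r2)
    return table
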