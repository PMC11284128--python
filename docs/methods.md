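# Methods

## Setting

`mrmediate` implements two-sample Mendelian randomization (MR) with a
mediation layer, the design used to ask whether an exposure (for
example the relative abundance of a gut-microbial taxon) affects a
binary disease outcome (for example a hydrocephalus subtype) partly
through a circulating mediator (for example an interleukin).  All
computation happens on GWAS summary statistics: per-SNP effect sizes,
standard errors, p-values and allele metadata from three independent
(non-overlapping) GWAS.  The package assumes the three standard
instrumental-variable conditions — instruments associated with the
exposure, independent of confounders, and affecting the outcome only
through the exposure — and provides diagnostics for violations of the
third (horizontal pleiotropy) rather than guarantees.

## Instrument selection

The pipeline order is fixed: p-value threshold (strict `<`, default
1e-5 for the primary screen and 5e-8 for the strict confirmation),
greedy LD clumping (r² > 0.001 within ±10,000 kb of the index SNP
removed; ties in p broken by chromosome, position, then rsID so the
result is independent of row order), weak-instrument exclusion at
F < 10, removal of SNPs more strongly associated with the outcome than
with the exposure (P_outcome < P_exposure, strict), harmonization with
unconditional removal of palindromic (A/T, G/C) SNPs, and finally a
user-supplied exclusion list standing in for confounder-database
lookups.  SNPs absent from the outcome are dropped rather than proxied;
no LD-proxy search is attempted.

Per-SNP variance explained defaults to r² = z²/(z² + n − 2), which
requires no allele frequency; with this choice the single-SNP
F statistic reduces exactly to z², so the F < 10 filter is equivalent
to |beta/se| < √10 and is always satisfied by SNPs passing the 1e-5
threshold.  The alternative 2p(1−p)β² (standardized continuous traits)
is available by option.  The set-level F uses the summed per-SNP r²,
the set size k and the median sample size, and is reported rather than
used as a filter, because the per-SNP form is the acting exclusion.

## Estimators

With ratio estimates θ_j = β_Yj/β_Xj and first-order SEs
se(θ_j) = se_Yj/|β_Xj|:

* **Wald ratio** (k = 1): θ with its first-order SE.  The first-order
  form is adequate here because instruments pass F ≥ 10 upstream.
* **IVW**: weighted regression of β_Y on β_X through the origin,
  weights 1/se_Yj²; identical to the inverse-variance-weighted mean of
  the θ_j.  Fixed-effect SE by default; when Cochran's Q has p < 0.05
  the model switches to multiplicative random effects, inflating the SE
  by max(1, √(Q/(k−1))) — heterogeneity re-models the estimate, it does
  not invalidate it.
* **MR-Egger**: the same regression with an intercept after orienting
  every SNP to β_Xj ≥ 0.  The slope is the pleiotropy-adjusted effect;
  the intercept estimates the average directional pleiotropic effect.
  SEs carry the overdispersion factor max(1, √(RSS/(k−2))).
* **Weighted median**: the θ_j are sorted; the estimate interpolates
  the weighted quantile function at cumulative weight 0.5 with
  percentile positions p_j = (Σ_{i≤j} w_i − w_j/2)/Σw.  SE by seeded
  parametric bootstrap (β_X and β_Y redrawn from their sampling
  normals), 1000 draws by default.
* **Simple / weighted mode**: the mode of a Gaussian kernel density of
  the θ_j (weights 1/se(θ_j)² for the weighted variant), with the
  normal-reference bandwidth 0.9·min(sd, IQR/1.349)·k^(−1/5) scaled by
  a bandwidth factor (default 1).  The mode is located on a 2048-point
  grid spanning the data ±3 bandwidths; SE by the same bootstrap.

OR-scale display uses exp(β) with exp(β ± 1.96·se) bounds; the constant
1.96 (not a re-derived quantile) keeps printed CI reproduction stable.
Two-sided p-values are 2Φ(−|β/se|), floored at 1e-300 so downstream
multiplicity corrections always receive values in (0, 1].

## Sensitivity suite

* **Cochran's Q** on the θ_j with weights β_Xj²/se_Yj² (equal to the
  IVW regression's weighted RSS), chi-square on k − 1 df.
* **Egger intercept test**: intercept, SE and two-sided p from the
  Egger fit (shared code path).
* **MR-PRESSO**: observed statistic RSS = Σ w_j (β_Yj − θ_(−j)β_Xj)²
  with leave-one-out IVW slopes θ_(−j) and w_j = 1/se_Yj².  The null is
  built from parametric draws of both β_X* and β_Y* (1000 by default,
  seeded), with leave-one-out slopes recomputed inside each draw.
  Monte-Carlo p-values carry the (1 + exceedances)/(n_sim + 1)
  correction, so they are never exactly 0.  Per-SNP outliers are
  Bonferroni-flagged at α/k; the distortion test compares the relative
  change in the IVW slope after removing the flagged SNPs against
  removals of random same-sized subsets (two-sided).  Outlier removal
  runs one remove-and-rerun round by default (configurable up to a
  fixed-point cap), and the gate consults the post-removal global test.
* **Leave-one-out**: k fixed-effect IVW fits each omitting one SNP; a
  SNP is flagged when its omission flips the sign or the 0.05
  significance of the estimate.

The decision gate calls a relationship positive only when the IVW p is
below 0.05, all computed methods agree in sign, the Egger intercept p
is ≥ 0.05, and the (post-removal) MR-PRESSO global p is ≥ 0.05.
Significant heterogeneity switches the IVW model rather than rejecting.

## Multivariable MR and mediation

MVMR regresses β_Y jointly on the per-SNP effect columns of m exposures
(no intercept, weights 1/se_Yj²); each coefficient is that trait's
direct effect.  The instrument matrix is the union of each trait's
selected instruments, clumped jointly with the minimum p across traits
as ranking key, restricted to SNPs present in every dataset, aligned to
the first trait's effect allele, palindromes removed.  SE
overdispersion uses max(1, √(RSS/(k−m))).  The Egger variant adds an
intercept after orienting SNPs to non-negative first-exposure effects;
the median variant solves weighted L1 regression by a smoothed
(majorize-minimize) IRLS to a 1e-10 relative tolerance with a 5000-
iteration cap — hard-clipped IRLS oscillates under heavy contamination,
and the smooth form is monotonically convergent.  Rank-deficient
designs raise a collinearity error naming the offending traits.

The two-step decomposition takes β_Total from univariable IVW
(exposure→outcome), β_XZ from univariable IVW (exposure→mediator), and
β_ZY as the mediator's MVMR direct effect adjusting for the one
exposure under study.  Mediated effect = β_XZ·β_ZY; proportion
mediated = mediated/β_Total, displayed as a percentage with two
decimals.  A mediating pathway exists only when mediated and total
effects share direction; sign(0) is inconsistent with any nonzero sign.
No CI is attached to the proportion: a delta-method interval is
deliberately not invented where the reference analysis reports none.

## Meta-analysis and multiplicity

Cross-cohort pooling is inverse-variance fixed-effect by default, with
DerSimonian–Laird (moment τ²) available; Q, its p, and
I² = max(0, (Q − df)/Q)·100 are reported in both models, and DL
reduces exactly to fixed-effect when Q ≤ df.  An exposure retains
causality when the pooled p is below 0.05.

FDR control is Benjamini–Hochberg within user-defined families.  The
grouping convention — microbial exposures by taxonomic rank per
outcome, mediators as their own factor family — is configurable
because reconstructed family sizes pin down the convention only at the
phylum level (m = 9 there reproduces the published adjustment exactly).
Calls are two-tier: *significant* when P < 0.05 and P_FDR < 0.1,
*potential* when P < 0.05 but P_FDR ≥ 0.1.

## Synthetic data: what it emulates and what it does not

The generator draws a chain X →(γ) Z →(δ) Y with direct effect τ, so
β_Total = τ + γδ and the true mediated proportion is γδ/(τ + γδ).  Per
SNP with MAF p, the true per-allele exposure effect is
N(0, exposure_effect_sd²), sampling SEs follow the standardized-trait
form 1/√(2p(1−p)N), observed effects add independent N(0, se²) noise
per GWAS, and p-values are exact two-sided normal tails (floored at
1e-300).  Binary outcomes are generated directly on the log-odds
summary-statistic scale — no individual-level case-control sampling —
because two-sample MR consumes only summary statistics.

Defaults define the validation conditions used throughout the tests:
100 exposure instruments and 100 mediator-specific instruments,
exposure/mediator GWAS of 10⁶, outcome GWAS of 2×10⁵, effect-size SD
0.1, MAF uniform on (0.05, 0.5), and the chain γ = 0.3, δ = −0.5,
τ = −0.2 (mediated proportion 42.9%).  The large discovery samples make
instruments strong, so exposure-side measurement error is negligible
next to outcome-side error; this is the regime in which IVW's nominal
coverage and the recovery targets are meaningful statements about the
estimators rather than about weak-instrument bias.

Mediator-specific instruments (SNPs affecting Z but not X) are part of
the generative model because without them every SNP's mediator effect
is exactly γ times its exposure effect, the MVMR design is collinear in
truth, and the mediator's direct effect is unidentifiable — the
two-step decomposition requires independent genetic variation in the
mediator.

Directional pleiotropy is planted *relative to the exposure-increasing
allele*: invalid SNPs add sign(b_j)·α_j, α_j ~ N(mean, sd²), to the
outcome effect.  This is the quantity the Egger intercept estimates
after its β_X ≥ 0 orientation; pleiotropy planted without the sign
convention cancels under orientation and is indistinguishable from
balanced pleiotropy.  Gross outliers shift the observed outcome beta by
±10 SEs.  Optional LD blocks (block size m, pairwise r² ρ, with a
matching LD-table generator) exercise clumping; SNPs are otherwise
independent and placed far apart.

Features of real summary data the generator does not emulate:
compositional microbiome abundance scales, case-control imbalance
(which makes real binary-trait SEs larger than the standardized-trait
formula), sample overlap between GWAS, population stratification, MAF-
dependent effect-size architecture, and realistic LD.  Passing recovery
tests therefore validates the estimators and the pipeline plumbing
under the stated model — they do not certify performance on real
cohorts.

One interaction worth knowing: the P_outcome < P_exposure instrument
filter preferentially removes SNPs with large pleiotropic outcome
effects.  That is arguably its purpose, but it means the Egger
intercept after the full pipeline under-recovers a planted pleiotropy
mean slightly; the intercept-recovery validation therefore runs the
pipeline with that filter disabled, isolating the estimator property.

## Numerical choices

* Monte-Carlo p-values use the +1 correction; bootstrap and simulation
  counts default to 1000 and are seeded — identical seeds give
  bit-identical results end to end.
* Validation is total at I/O: a summary-statistics file either parses
  into a fully valid object or raises an error citing the offending
  column or line; numeric fields round-trip at 17 significant digits.
* Clumping treats missing LD entries as r² = 0 (kept, logged).
* Degenerate inputs: k = 1 harmonized sets fall back to the Wald ratio;
  k < 3 skips Egger/median/mode; k < 4 skips MR-PRESSO; empty
  harmonized sets raise an explicit signal that screens record as
  skipped rather than aborting.
* Problem sizes in the validation suite (20–100 SNPs, 50–2000
  replicates per property) were chosen as the smallest at which the
  Monte-Carlo bands are informative for the properties being checked.

## Known limitations

No Steiger directionality filtering, LD-proxy substitution, MR-RAPS or
contamination-mixture estimators; one mediator per mediation model;
no delta-method CI for the mediated proportion; reverse analyses of a
strongly caused outcome can pick up the forward signal through the
outcome's borrowed instruments (a known limitation of bidirectional MR
without directionality filtering).
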