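# Methods

## Scope and model

`medax` implements the genetic-epidemiology core of a gallstone
microbiota–metabolite analysis as a reusable library: two-sample
summary-data Mendelian randomization (MR) with a battery of estimators and
sensitivity diagnostics, a two-step mediation decomposition, a
random-effects meta-analysis of odds ratios, and cross-omics
correlation/Mantel statistics. Individual-level data never enter the
package; every MR quantity is computed from per-SNP association summaries
(β̂, SE, EAF, N) of exposure, mediator and outcome GWAS.

The causal model is the standard instrumental-variable one: a SNP j with
per-allele effect γ_j on the exposure is a valid instrument when it is
associated with the exposure (relevance), independent of confounders, and
affects the outcome only through the exposure (exclusion restriction). Under
a linear model with causal effect θ, the outcome association is
β_yj = θ·γ_j + α_j, where α_j is a pleiotropic shift (zero for valid
instruments). The estimators differ in which assumptions about {α_j} they
need.

## Instrument selection and QC

Stages run in this order, each a subsequence filter: p-value tier →
LD clumping → F filter → confounder screen → harmonization.

* **p-value tiers.** Defaults 1e-5 for microbiome exposures, 5e-6 for
  metabolite exposures, 5e-8 (genome-wide) for the disease trait used as an
  exposure in the reverse direction. Strict inequality: p equal to the
  threshold is excluded.
* **Clumping.** Greedy: the smallest-p remaining SNP becomes an index and
  removes every remaining SNP on its chromosome within ±10,000 kb with
  r² ≥ 0.001 against it. The window test precedes the r² test, so spurious
  cross-chromosome r² entries never prune. Ties on p break by position then
  rsid, for determinism. The package consumes a precomputed r² matrix
  (TSV); pairs absent from the panel are treated as r² = 0 and logged.
  Shipping or computing a reference LD panel is out of scope.
* **Instrument strength.** Per variant,
  R² = 2·EAF(1−EAF)β² / (2·EAF(1−EAF)β² + 2·EAF(1−EAF)·SE²·N) and
  F = R²(N−2)/(1−R²). Variants with F < 10 are removed; F exactly 10 is
  kept. F uses each variant's own R² and that trait's N, not a cumulative
  R².
* **Confounder screen.** A (SNP, TRAIT, P) table of known-confounder
  associations (obesity/BMI, type 2 diabetes, smoking, alcohol, coffee,
  …); any SNP with an association at p < 1e-5 is removed and logged with
  the trait names.
* **Harmonization.** Outcome records are aligned to the exposure effect
  allele; swapped reports are sign-flipped and frequency-complemented,
  strand-complement reports (A/G vs T/C) are reconciled before a SNP is
  dropped. Palindromic variants (A/T, C/G) with exposure MAF > 0.3 are
  dropped as strand-ambiguous; those at or below the limit are oriented by
  allele-frequency agreement (flip when the outcome EAF is closer to
  1−EAF_exp than to EAF_exp). Duplicate rsids keep the smallest-p row.
  Irreconcilable allele pairs are dropped and logged, never fatal.

The F filter is applied after selection/clumping and before harmonization.

## Estimator battery

With w_j = 1/se²_yj:

* **IVW** (primary): β̂ = Σw_jβ_xjβ_yj / Σw_jβ²_xj, the weighted regression
  of β_y on β_x through the origin. Default variant is multiplicative
  random-effects: the fixed-effect SE is scaled by max(1, √(Q/(n−1))), so
  heterogeneity can widen but never shrink the interval. A single-SNP set
  reduces to the Wald ratio β_y/β_x with first-order SE se_y/|β_x|.
* **MR-Egger**: the same regression with a free intercept, after
  re-orienting SNPs so β_x ≥ 0. The intercept estimates the mean
  directional pleiotropy (valid under InSIDE: pleiotropy independent of
  instrument strength); the slope is the pleiotropy-adjusted effect.
  Residual scale is floored at 1 as in the IVW variant.
* **Weighted median**: the weight-interpolated 50th percentile of the
  per-SNP ratios β_yj/β_xj, weights inverse to the first-order ratio
  variance se²_yj/β²_xj. Consistent while ≥ 50% of weight comes from valid
  instruments. SE by a seeded nonparametric SNP bootstrap (default 1000
  draws).
* **Simple mode**: argmax of a normal-kernel density over the ratios,
  bandwidth = φ × Silverman's plug-in rule (φ = 1 by default); SE by the
  same bootstrap. Chosen as the simple (unweighted) mode variant; which
  variant the original analysis used is not documented, so this is a
  package decision.
* **Cochran's Q**: Q = Σw_j(β_yj − β̂β_xj)², df = n−1, chi-square upper
  tail.
* **MR-PRESSO-style global/outlier test**: the observed residual sum of
  squares is built from leave-one-out IVW fits (each SNP's weighted
  residual taken against the slope estimated without it) and compared to a
  null distribution from parametric draws β*_yj ~ N(β̂_loo,j·β_xj, se²_yj)
  (default 1000, seeded); p-values use the (1+count)/(n_sim+1) convention.
  Per-SNP outlier p-values are Bonferroni-corrected over n_snp; when
  outliers exist the IVW estimate is recomputed without them. This follows
  the published residual-simulation idea but is this package's own
  formulation, not a port of the reference R implementation.

All p-values are two-sided normal except Q (chi-square). 95% CIs use
z = 1.959964. A link is **reliable** when IVW p < α (0.05) and the IVW,
weighted-median, Egger-slope and PRESSO-corrected (when produced) estimates
agree in sign. The bidirectional wrapper runs the battery both ways
(the reverse direction selected at the genome-wide tier) and labels the
pair `unidirectional` when only the forward link is reliable.

Sets too small for a method degrade gracefully (n ≥ 2 for Q, ≥ 3 for
Egger/median/mode, ≥ 4 for PRESSO); skipped methods are recorded and
excluded from the concordance check.

## Mediation

Given IVW estimates β₁ (exposure→mediator), β₂ (mediator→outcome) and
β_all (exposure→outcome): indirect = β₁β₂, direct = β_all − β₁β₂,
proportion mediated = (β₁β₂)/β_all. The proportion is reported as a
magnitude percentage with a sign-consistency flag, because an indirect and
total effect of opposite sign ("inconsistent mediation") has no clean
percentage interpretation. Its SE is the delta method on the product and
ratio — Var(β₁β₂) ≈ β₂²se₁² + β₁²se₂², Var(ratio) ≈ (Var(ind) +
ratio²·se_all²)/β_all² — and the 95% CI is truncated to [0, 100]%. The
CI construction for the published intervals is not documented; the
truncated delta method reproduces their hard zero floor. β₂ comes from
univariable MR of the mediator on the outcome; multivariable adjustment is
out of scope. The two-step wrapper attempts the decomposition only when
both step links pass the reliability rule.

In the pipeline, step-2 instruments are additionally made disjoint from
the selected exposure instruments: a SNP that instruments the exposure and
reaches mediator significance carries the exposure's direct path into the
mediator→outcome ratio and would bias β₂ upward.

## Meta-analysis

Study odds ratios arrive as OR with 95% CI; y_i = ln(OR_i) and
se_i = (ln(hi)−ln(lo))/(2·1.959964). Fixed-effect inverse-variance weights
give Q and I² = max(0,(Q−df)/Q)·100. Between-study variance τ² by
DerSimonian–Laird moments (default) or REML (bounded 1-D optimisation,
xatol 1e-12); pooled weights 1/(se²+τ²); CI on the log scale,
exponentiated. No Hartung–Knapp adjustment. DL and REML differ in the
third decimal of the pooled OR on the four-study dietary-inflammatory-index
table; both are exposed because the published analysis does not name its
τ² estimator.

## Integration statistics

`correlate` computes all cross-table Pearson or Spearman correlations
(Spearman = Pearson on within-column ranks; p-values from the t transform,
matching scipy), applies Benjamini–Hochberg over the full pair family, and
flags edges with |r| > 0.7 and p < 0.05 — the BH q-values are computed
before the edge filter, and nothing is dropped from the output table.
`mantel` correlates the upper triangles of two distance matrices; the
one-sided (greater) p-value comes from simultaneous row/column permutations
of one matrix with the (1+count)/(n_perm+1) correction, or from exhaustive
enumeration of all n! relabelings (`exact=True`, n ≤ 8), where the p-value
is the exact fraction including the identity. Distance construction is
caller-supplied; Euclidean and Bray–Curtis builders are provided.

## Synthetic-data generators

The generators define the study conditions under which the package is
validated; their defaults are fixed, not tuning knobs.

* **Two-sample GWAS.** Standardized (unit-variance) phenotypes, so
  se = 1/√(2·maf(1−maf)N) in closed form. Defaults: 50 SNPs, N = 200,000
  per trait (biobank scale), MAF ~ U(0.05, 0.5), per-allele effects
  half-normal with scale 0.05 — instruments comfortably beyond F = 10, as
  the selection step produces in practice. Effects are reported on the
  trait-increasing allele orientation; directional pleiotropy
  (α ~ N(μ_α, σ_α²) on a configured fraction of SNPs) is defined on that
  shared orientation, which is what makes the Egger intercept estimand
  μ_α well-defined. Observed β̂ add Gaussian sampling noise at the
  closed-form SE; p-values are two-sided normal; the LD matrix is
  block-diagonal with configurable within-block r². The truth record keeps
  every latent draw, so each observation's conditional mean can be
  regenerated exactly.
* **Mediation.** Two disjoint SNP panels: panel A instruments the exposure,
  panel B the mediator. Effects propagate along the chain (mediator at A:
  θ₁γ_j; outcome at A: (direct+θ₁θ₂)γ_j; outcome at B: θ₂δ_k), so the true
  total is direct + θ₁θ₂ and the true proportion mediated is θ₁θ₂/total.
* **Omics tables.** Planted taxon–metabolite pairs share a latent factor
  scaled so the expected correlation equals the target; a group shift
  (default 1.5 SD across 8 + 8 samples) moves planted taxa down and their
  paired metabolites coherently with the correlation sign, emulating
  protective taxa inversely associated with risk metabolites. Non-planted
  features are independent noise.

What these generators do **not** emulate: compositionality and
zero-inflation of real abundance data, realistic LD decay, sample overlap
between GWAS, winner's-curse from selecting instruments in the same sample,
and binary-outcome (logistic) effect scales. Passing recovery tests
therefore demonstrates correctness of the estimators under their stated
assumptions, not robustness to those real-data features.

All generators split independent substreams from one root seed
(`numpy` `SeedSequence.spawn`), so identical configs give byte-identical
outputs and sub-simulations are separately reproducible.

## Numerical choices and degenerate inputs

* z = 1.959964 everywhere a 95% CI or SE↔CI conversion appears.
* Bootstrap SE of 0 (all ratios identical) yields a point-mass estimate
  with a tiny positive SE rather than a division error.
* Weighted-median interpolation uses the cumulative-midpoint convention
  (cum_j − w_j/2), clamping to the extreme ratios outside the grid.
* Mode-search grid: 512 points over the ratio range.
* Permutation-tie comparisons use a 1e-12 slack so the identity permutation
  always counts.
* Clumping and selection are deterministic under ties (p, then position,
  then rsid).
* Validation errors carry the offending SNP/row; harmonization and
  screening failures are logged and skip the variant rather than aborting.

## Problem sizes used in the test suite

Oracle-equivalence tests enumerate instances of ≤ 6 SNPs against explicit
summation/normal-equation oracles. Calibration properties use the
generator defaults: IVW bias over 100 replicates, type-I error over 1000
null replicates (accepted band 5% ± 2%), outlier recovery over 100
replicates with a 10·SE implanted shift, mediation recovery over 200
replicates at 30% true mediation, and planted-edge recovery over 50 (tests)
/ 100 (median-correlation check) seeds. The whole suite runs in well under
a minute on one CPU.

## Known limitations

* The mode estimator is the simple (unweighted) variant only.
* MR-PRESSO here is the leave-one-out formulation described above;
  numerical agreement with the reference R package is not claimed.
* No multivariable MR, Steiger filtering, or correlated-instrument IVW.
* Meta-analysis covers DL/REML random effects only — no Hartung–Knapp,
  subgroup, meta-regression or publication-bias machinery.
* The proportion-mediated CI ignores covariance between the three IVW
  estimates (they come from separate instrument sets, where independence
  is the natural approximation).
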