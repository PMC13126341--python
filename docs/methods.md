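# Methods

`mrchain` implements a summary-statistics causal-inference workflow for
molecular epidemiology: two-sample Mendelian randomization (MR) with a
battery of sensitivity diagnostics, followed by two-step MR mediation and a
network screen that assembles upstream-protein → mediator-protein →
metabolite → disease regulatory axes. This note records the models, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions.

## Two-sample MR model

Each genetic variant *j* supplies a marginal association with the exposure
(β̂ₓⱼ, σₓⱼ) estimated in one cohort and with the outcome (β̂ᵧⱼ, σᵧⱼ)
estimated in a disjoint cohort. Under the instrumental-variable assumptions
the per-SNP Wald ratio β̂ᵧⱼ/β̂ₓⱼ estimates the causal effect θ, and the
estimators combine ratios as follows.

- **IVW** (primary): the zero-intercept weighted regression of outcome on
  exposure betas with weights 1/σᵧⱼ², equal to the inverse-variance-weighted
  mean of Wald ratios. The SE carries a multiplicative residual dispersion
  floored at 1 (*multiplicative random-effects*). The floor matters: under
  homogeneity the dispersion estimate is χ²ₖ₋₁/(k−1)-distributed and dips
  below 1 half the time; flooring prevents anti-conservative SEs. A
  fixed-effect variant is available by flag. p-values use the normal
  approximation.
- **MR-Egger**: weighted regression with a free intercept after orienting
  all exposure betas non-negative; the intercept estimates average
  directional pleiotropy. Coefficient p-values use the t distribution with
  k−2 df; the dispersion is floored at 1 as for IVW, which makes the
  intercept test mildly conservative under exact homogeneity (observed
  type-I error ≈3–5% at the 5% level in the calibration suites) and
  correctly sized once any real dispersion is present.
- **Weighted median**: interpolated weighted median of Wald ratios with
  inverse-variance weights; consistent when ≥50% of the weight comes from
  valid instruments. SE by seeded parametric bootstrap (default 1000
  resamples of both betas from their sampling distributions).
- **Simple/weighted mode**: mode of the Gaussian-kernel-smoothed density of
  Wald ratios, unweighted or inverse-variance weighted. Bandwidth is
  `bandwidth_factor × 0.9 · min(SD, IQR/1.349) · k^(−1/5)` with factor 1 —
  a Silverman-style rule on a robust spread, stated explicitly because mode
  estimators are bandwidth-sensitive and no canonical tuning exists. SEs by
  the same parametric bootstrap.

The Wald-ratio SE is first-order (σᵧ/|β̂ₓ|); the second-order term is
negligible at the instrument strength the pipeline enforces (F ≥ 10).
Odds ratios are exp(β) with Wald 95% CIs, appropriate when outcome betas
are log-odds ratios from a binary-trait GWAS.

## Instrument selection and harmonization

Selection applies, in order: genome-wide significance (p < 5×10⁻⁸), minor
allele frequency ≥ 0.01 (effect-allele frequency folded), greedy LD
clumping (r² < 0.1 within 10,000 kb, index SNPs taken in ascending-p order,
ties broken by position then id for determinism), and per-SNP
F = (β/σ)² ≥ 10. Every excluded SNP is logged with the first rule that
removed it, so selection never silently loses a variant. SNPs absent from
the LD panel are kept and treated as independent with a warning (strict
mode drops them); MAF ordering relative to clumping is fixed by this
implementation since sources describing this filter sequence are ambiguous
about it.

Harmonization aligns outcome records to the exposure's effect allele:
identical or strand-complement alleles are kept, swapped or
complement-swapped alleles are flipped (outcome beta negated, EAF
complemented), anything else is dropped as incompatible. Palindromic (A/T,
C/G) SNPs cannot be oriented from allele labels, so they are oriented
purely from allele frequencies: dropped when either EAF is missing or
within 0.5 ± 0.08 (the common community ambiguity band; configurable), kept
when both EAFs sit on the same side of 0.5, flipped when on opposite sides.

## Sensitivity diagnostics and the retention gate

- **Cochran's Q** on Wald ratios around the fixed-effect IVW mean;
  χ²ₖ₋₁ under homogeneity.
- **Egger intercept test** for directional pleiotropy.
- **MR-PRESSO**: the observed leave-one-out weighted residual sum of
  squares is compared with a parametric null (default 5000 simulations of
  both betas under the fitted outlier-free model); per-SNP residuals give
  outlier p-values thresholded Bonferroni-style at 0.05/k; when outliers
  are found the IVW estimate is recomputed without them, and a distortion
  test compares the observed shift against removals of random same-size
  subsets of non-outliers.
- **Steiger directionality**: per-instrument variance explained from the
  squared correlation implied by the Wald statistic, r² = t²/(t²+n−2),
  summed over instruments for each trait; direction is TRUE when the
  exposure sum exceeds the outcome sum, with a z-test on the difference of
  Fisher-transformed pooled correlations. For binary outcomes this r² is a
  liability-scale approximation. The implied-r² route is used whenever
  betas and SEs are present.
- **Leave-one-out** IVW refits, flagging omissions that change the sign or
  cross the 0.05 boundary.

The screening gate retains an exposure when all enabled criteria hold:
heterogeneity (Q p > 0.05, waived under random-effects IVW, which is the
default), no directional pleiotropy (intercept p > 0.05), MR-PRESSO
(global p > 0.05, or no outliers flagged, or outlier-corrected estimate
sign-concordant with the original), and Steiger direction TRUE. Each
criterion is individually switchable. The lead SNP reported per edge is
the smallest-p retained instrument — a reporting convention, not an
analytic choice.

## Two-step mediation

For exposure → mediator → outcome, the mediated effect is β₁₂ = β₁·β₂ with
first-order delta-method SE √(β₁²σ₂² + β₂²σ₁²); the two legs are treated as
independent, as in a two-sample design with distinct instrument sets and
cohorts. The exact-product variance (adding σ₁²σ₂²) is available by flag;
the difference is <2% once both legs exceed |β/σ| ≈ 3. The mediated
proportion is β₁₂/β_all. Its CI divides the β₁₂ CI by a fixed β_all by
default; a full delta-method ratio CI that propagates σ_all is available
(`propagate_total`) — the fixed-denominator form is the default because it
is the more common reporting convention and the two coincide when the
total effect is precisely estimated. Screening keeps mediations with
p < 0.05 and proportion > 15%, ordered by ascending p; negative
(inconsistent) proportions never pass. p-values are not adjusted for
multiple comparisons by default, matching the single-axis discovery
setting; an FDR step can be applied downstream if desired.

## Network screen and the combined upstream/downstream rule

Edges are screened per layer (proteins vs outcome, upstream vs downstream
proteins, proteins vs metabolites, metabolites vs outcome); an edge passes
when IVW p < 0.05, the gate is satisfied and Steiger direction is TRUE.
The layer significance threshold is nominal 0.05 — the screening stage's
job is ranking candidates, and instrument-level stringency already lives
in the 5×10⁻⁸ selection. β_all, β₁ and β₂ always come from IVW (the primary
estimator); the other estimators are diagnostics.

An upstream→mediator axis is retained only when (i) both proteins pass
against the outcome, (ii) the upstream mediation passes the screen, and
(iii) at least one screened metabolite mediation supports the
mediator→outcome leg. Rule (iii) — the combined upstream-and-downstream
criterion — excludes protein pairs lacking a downstream mechanism.
Per-exposure seeds are derived from the global seed and the exposure/layer
names (CRC32-keyed), so results are independent of input ordering and
byte-reproducible.

## Synthetic-data generator

`simulate_cohort` draws genotypes Binomial(2, MAF) independently per SNP
(MAF uniform on [0.05, 0.5]) for three disjoint cohorts and builds traits
from the chain X = Gγ + e, M = θ₁X + e, Y = direct·X + θ₂M + Gα + e, so
the true total effect is direct + θ₁θ₂. Summary statistics are per-SNP
marginal simple regressions within each cohort (logistic for binary
outcomes, so betas are log-odds ratios; baseline prevalence defaults to
5.6%, a realistic figure for a chronic-disease registry phenotype).
Defaults — 30 SNPs, n = 5000 per cohort, per-SNP instrument effects
N(0, 0.15) on a unit-noise trait — give per-SNP R² of a few percent and
mean F well above 10, the regime of strong cis-pQTL instruments.

Pleiotropy α is assigned to a configurable fraction of SNPs,
N(mean, sd) *oriented by the instrument's sign*: a directional (nonzero
mean) effect is aligned with the exposure-increasing allele, which is the
quantity the Egger intercept estimates after orientation; a zero-mean α is
balanced pleiotropy. Artifact injection rewrites a fraction of SNPs to
palindromic allele pairs (half losing their outcome EAF) and multiplies
the outcome beta of `n_outliers` SNPs by a factor. Outliers are injected
among instrument-grade SNPs (exposure p < 5×10⁻⁸): an outlier on a variant
that never reaches the estimator tests nothing. An optional block-LD mode
(Gaussian-copula haplotypes) emits a matching empirical LD panel from an
independent reference cohort for clumping tests. One global seed fans out
to per-stage child streams so each cohort is independently reproducible.

`simulate_chain` extends this to four traits (U → M → Z → Y) with disjoint
trait-specific SNP blocks. Its defaults form a *pure chain* (both direct
effects zero, θ₁ = 0.6, φ₁ = 0.45, φ₂ = 0.55, instrument SD 0.35): every
SNP then acts on all downstream traits proportionally, so instrument sets
selected at genome-wide significance remain valid even when a strong
upstream SNP reaches significance on a downstream trait, and both mediated
proportions are 100% — complete mediation, the cleanest recoverable axis.
Partial mediation (nonzero direct effects) is configurable and is used in
tests of the screening floor.

What the generator does **not** emulate: realistic genome-wide SNP counts
or effect-size distributions, LD beyond exchangeable blocks, sample
overlap, population stratification, covariates or sex chromosomes.
Passing recovery tests therefore demonstrates correctness of the
estimators and the screening logic under the stated model, not robustness
to every failure mode of real cohort data.

## Problem sizes in the verification suites

The recovery and calibration suites use sizes chosen to make the sampling
error of each checked rate small relative to its acceptance band: IVW
recovery with 30 instruments and n = 5000 per cohort over 100 seeds;
Q/Egger type-I-error calibration with 20 SNPs and n = 2000 over 1000 seeds
each; MR-PRESSO detection of a single 10× outlier (true effect 0.3,
instrument SD 0.35 — strong enough that a 10× inflation of the outcome
beta is genuinely an outlier rather than a perturbation of a near-zero
value) over 50 seeds; end-to-end axis rediscovery over 50 seeds. The
`scripts/acceptance.py` entry point re-runs all of these from scratch.

## Numerical conventions and degenerate inputs

Weighted-median interpolation uses standardized cumulative weights
(cum − w/2)/Σw with linear interpolation at 0.5. Mode estimation evaluates
the kernel density on a 512-point grid spanning the ratio range ± 3
bandwidths; identical ratios short-circuit to that value. A single
harmonized pair delegates IVW to the Wald ratio; fewer than 3 pairs skips
Egger/median/mode, fewer than 4 skips MR-PRESSO, and these appear as
not-applicable (NaN) in reports rather than errors. Zero exposure betas
are rejected by ratio-based estimators. Bootstrap and MR-PRESSO results
are bit-reproducible under a fixed seed. Empirical p-values use the
(r+1)/(n+1) convention so they are never exactly zero.

## Known limitations

- The Steiger liability-scale handling of binary outcomes is an
  approximation; no exact liability transform is attempted.
- MR-PRESSO's distortion-test null uses same-size random removals of
  non-outliers, a simplification of the original bootstrap scheme.
- LD clumping is genome-wide within windows keyed by variant position;
  no per-chromosome restriction beyond the chromosome match itself.
- The proportion-mediated CI does not propagate uncertainty in β_all by
  default (see above); proportions from weak total effects should be read
  with the `propagate_total` variant.
- No multivariable MR, colocalization, MR-RAPS or contamination-mixture
  models; the estimator set is deliberately the five classical ones plus
  their standard diagnostics.
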