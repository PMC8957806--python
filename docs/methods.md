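# Methods

This note records the models, conventions and numerical choices behind
`ctprs`, and what the synthetic-data tests do and do not demonstrate.

## Score construction

**INFO filter.** Imputation quality is filtered with a strict inequality
(`info > 0.9` by default), matching the usual reading of "INFO > 0.9";
the cutoff is configurable.

**Variant QC.** A variant survives when *all* of: call rate > 0.95,
MAF > 0.01, Hardy-Weinberg p > 1e-6, and (when a reference frequency is
supplied) |AF − ref AF| ≤ 0.20. MAF and call rate are strict, the
frequency difference inclusive, following the stated cutoffs. Removal
counts are attributed to the first failing criterion in that order purely
for reporting; survivorship is a conjunction and therefore
order-independent and idempotent. HWE uses the 1-df goodness-of-fit
chi-square on best-guess hard calls (dosages rounded to nearest integer);
a conditional exact test is available (`method="exact"`). The chi-square
is anticonservative at small minor-allele counts, so the two can disagree
when both p-values sit within a couple of decades of the cutoff — the QC
report makes the chosen method explicit. Monomorphic variants get p = 1
with a flag.

**Harmonization.** Matching is by variant id with a chrom:pos fallback.
Exact allele matches keep β; swapped alleles negate it; strand-complement
matches are complemented and re-matched; A/T and C/G pairs cannot be
disambiguated from strand flips and are dropped by default (imputed,
INFO-filtered panels make the loss small). Flipping which allele a target
variant counts changes the standard score only by the additive constant
2·Σβ_flipped, so downstream AUCs are exactly invariant — this is asserted
in the tests.

**APOE mask.** chr19:45,111,942–45,711,941 (1-based, inclusive on both
ends), i.e. ±300 kb around the APOE ε-coding SNPs, is removed before
clumping so the score cannot ride on the APOE signal.

**Clumping.** Greedy: repeatedly take the smallest-p unassigned variant as
index (ties broken by position, then id, making output deterministic),
then assign to its clump every unassigned same-chromosome variant within
±250 kb whose r² with the index exceeds 0.1. r² is the squared sample
correlation of dosages over pairwise-complete samples, computed from the
target cohort itself (no external LD reference panel is required; one can
be supplied by passing its genotypes instead). Zero-variance columns give
r² = 0 with a flag. The index p-value cutoff defaults to 1.0 (retain all
indices). The retained set is an LD antichain: no two retained variants
within one window exceed the r² threshold.

**Thresholding.** `p ≤ threshold`; the canonical sweep is the 14 values
0.5, 0.4, 0.3, 0.2, 0.1, 0.05, 0.01, 0.005, 0.001, 1e-4 … 1e-8. The ≤
convention is a documented choice; the boundary case is tested.

**Scoring.** Standard: Σβ·X. Risk-increasing: each variant is reoriented
so β > 0 (G = 2 − X when β < 0), and the score (Σβ⁺G)·T/Σβ⁺ reads as an
effective risk-allele count in [0, 2T]. The denominator sums the
*reoriented positive* betas: a signed sum could be zero or negative,
making the score undefined, and only the positive-orientation reading
yields the "average risk-allele" interpretation. Variants with β exactly 0
have no risk orientation and are excluded from T and Σβ with a flag. The
zero substitution for missing data applies to the contribution itself
(G = 0, not 2 − 0): a zero score is the stated approximation for the
common genotype. Standardization uses the sample-SD (n−1) convention.
Association models consume the standardized standard score ("per SD");
survival reports additionally quote the risk-increasing score
unstandardized ("per risk allele").

## Case/control evaluation

Logistic models are maximum-likelihood fits (statsmodels IRLS) with Wald
SE/p; perfect separation is flagged and refit with a vanishing ridge so
coefficients remain reportable; rank-deficient designs raise an error
naming the collinear terms. AUC is in-sample (no cross-validation),
computed as the normalized Mann-Whitney statistic with ties counting ½.
Threshold selection maximizes the standardized PRS coefficient (largest
effect size, not smallest p); exact ties go to the smaller threshold.

The DeLong comparison of two correlated AUCs uses placement values and
their empirical covariance; two-sided by default; degenerate variance
(identical predictors) returns p = 1 by convention. Its null calibration
and agreement with a paired bootstrap are part of the acceptance tests.

The case/control score comparison is a one-sided Welch t-test
(case mean > control mean); the unequal-variance form is a deliberate
choice where the classical test is unspecified.

PCA runs on the QC-passed clumped variant set: dosages mean-imputed,
centered at 2p̂ and scaled by 1/√(2p̂(1−p̂)), then SVD; each component's
largest-magnitude loading is made positive, so output is bit-reproducible.
The ε3/ε3 stratum keeps APOE genotype 33 only and drops the (now
constant) ε4-count term from designs.

## Survival analysis

The time axis is **age**, with delayed entry at study enrolment: the risk
set at event age t is {entry < t ≤ exit}. The Cox partial likelihood is
maximized by Newton-Raphson with step halving (convergence when the score
norm < 1e-10), using suffix-sum risk-set accumulation so each iteration is
O(n log n). Tie handling is Breslow by default with Efron behind a flag;
the generator produces continuous ages, so ties only arise in degenerate
fixtures. Wald 95% CIs on exp(β) are reported per term, and the model
p-value is the likelihood-ratio test against the null. With entry ages all
zero the fit coincides with a classical right-censored Cox fit (verified
against lifelines to 1e-6).

Kaplan-Meier curves use the product-limit estimator with delayed-entry
at-risk counts; a group's curve starts at the first event age where its
at-risk count reaches a configurable minimum (default 1). The k-group
log-rank test uses the same delayed-entry risk sets with the
hypergeometric covariance and df = k−1; zero events raise an explicit
"undefined" error that the pipeline records rather than masks.

Tertiles cut at the empirical 33.33%/66.67% quantiles (linear
interpolation); boundary values go to the lower group, so 10 samples split
4/3/3.

## Synthetic cohorts: what they emulate

`SimulationConfig` defaults describe the study conditions: 2,000 samples ×
5,000 variants in LD blocks of 10, within-block dosage correlation 0.7,
MAF ~ U(0.05, 0.5) shared within a block, causal fraction 0.05 with
per-causal-variant liability SD 0.02, GWAS noise from an effective
discovery size of 170,000, depression prevalence 0.36 within the LOAD
sample, and covariate marginals plausible for an LOAD cohort
(age ~ N(81.5, 6.7²), 68% female, education ~ N(16.2, 3.7²), APOE ε4 count
distribution ≈ 64/33/3%, ordinal childhood financial need). All are
overridable.

**LD generation.** Alleles are thresholded latent Gaussians with
block-exchangeable correlation. Because thresholding attenuates
correlation, the latent correlation is calibrated numerically (a
tetrachoric-style inversion at the block's allele frequency) so that the
*realized dosage* correlation matches `within_block_r`; without the
calibration a nominal 0.9 would deliver r² ≈ 0.49 instead of 0.81. One
frequency per block keeps the inversion exact. The variant map (ids,
GRCh37-like positions, alleles, MAFs) is drawn from a separate `map_seed`
so several cohorts can be simulated against one GWAS truth, like two
cohorts genotyped on a shared panel; chr19 blocks start at 45.12 Mb so the
APOE mask is always exercised.

**Phenotype.** Liability = √V_g·z(genetic score) + Σ coef·z(covariate) +
N(0,1), with V_g = n_causal·effect_sd², so the genetic variance share is
the closed form V_g/(V_g + V_cov + 1) — the liability-model AUC oracle in
the acceptance tests depends on this being exact. Cases exceed the normal
quantile implied by the prevalence.

**Onset.** Exponential proportional hazards on the age axis from an onset
origin (65 y): hazard = baseline · exp(log-HR · z(score)). Subjects whose
onset precedes study entry are redrawn conditional on onset > entry;
because the exponential is memoryless that conditional draw is exactly
entry + Exp(hazard) and is performed in closed form (a literal rejection
loop is equivalent but can take astronomically many draws for old,
high-hazard subjects). The incidence of depression over follow-up is not
calibrated to any real cohort — the baseline hazard (0.05/person-year) and
uniform 1–12-year follow-up are free parameters chosen to give a ~30%
event rate.

**What passing tests do not show.** The generator has exchangeable LD
blocks, a single homogeneous population (a 2-subpopulation mixture is used
only in the PCA tests), no imputation-error structure beyond a uniform
INFO column, no indels or duplicated ids, and hazards constant in age.
Calibration and recovery results therefore demonstrate correctness of the
estimators under the stated models, not performance on real ROSMAP/NACC
data, whose headline AUCs require restricted individual-level access and
are out of scope here.

## Problem sizes and determinism

Default test/acceptance sizes (2,000 × 5,000 end-to-end; n = 20,000 for
the liability and logistic recovery checks; 2,000 replicates for log-rank
calibration; 500 seeds for DeLong calibration) were chosen so the whole
suite completes in a few minutes on one core while keeping Monte-Carlo
error well inside each assertion's band. One global seed fans out to named
substreams (map/genotypes/truth/sumstats/phenotype/onset), so any stage is
regenerable independently and identical seeds give identical bytes; the
pipeline manifest embeds a sha256 of every output file, making
end-to-end byte-reproducibility testable.
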