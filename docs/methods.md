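# Methods

`jackmr` implements and evaluates block jackknife resampling Mendelian
randomization (MR): one-sample instrumental-variable analysis in which the
polygenic-score instrument is built by cross-fitting, so that no
participant's data enter the genome-wide scan that produced their own score
weights.  This note records the model, the estimators, the design choices
that were genuinely open, and what the simulations do and do not show.

## The problem

One-sample MR instruments an exposure X with a weighted allele score
(PRS) and estimates the causal effect on an outcome Y by two-stage least
squares (2SLS).  When the same individuals are used to discover the SNPs,
estimate their weights, and run the MR regression ("overlapping sample"),
the score partially fits the within-sample noise of X: the instrument looks
stronger than it is (inflated instrument–exposure R²), and because the
weight-estimation noise is correlated with the confounder's contribution to
X, the 2SLS estimate inherits a bias in the direction of the confounded
ordinary-least-squares slope, with over-precise standard errors.  This is
the joint effect of winner's curse and sample-overlap overfitting.

Block jackknife resampling removes the overlap without an external cohort:

1. randomly split the n individuals into `n_block` balanced blocks;
2. for each block b, run the exposure GWAS on everyone *except* block b;
3. select SNPs at a P-value threshold and score the members of block b with
   those weights;
4. pool all blocks and use the assembled score as a single instrument in
   one 2SLS over the full sample.

Per-block SNP sets and weights legitimately differ; the assembled score is
intentionally heterogeneous across blocks.  The structural guarantee — block
b's weights are invariant to anything about block b's members — is tested
directly.

## Generative model

Cohorts are simulated with m independent biallelic SNPs, dosages
G_ij ~ Binomial(2, af), and phenotypes

    X = Σ_j b_j G_j + β_UX·U + ε_X,      U ~ N(0, 1)
    Y = β_XY·X + β_UY·U + ε_Y            (applied cohorts only)

Defaults (the study conditions): n = 50 000 per cohort, m = 500, af = 0.2,
total genetic variance Var_exp = 0.1, β_XY = 0.2, β_UX = 0.4, β_UY = 0.3,
10 jackknife blocks, and 13 selection thresholds from 5×10⁻⁸ to 1.

Per-SNP effects: only the total Var_exp is fixed by the study design; the
per-SNP distribution is a modelling choice.  The default draws raw effects
from a standard normal and rescales so Σ_j 2·af·(1−af)·b_j² = Var_exp holds
exactly (the convention of variance-budget phenotype simulators); an
`equal` mode (all SNPs identical) is available.  The choice matters a great
deal for threshold selection: under equal effects each SNP carries a
non-centrality of ~10 at n = 50 000 and essentially nothing survives
P ≤ 5×10⁻⁸, whereas under gaussian effects the variance concentrated in the
upper tail yields ≈50 genome-wide-significant SNPs capturing ≈0.04 of the
exposure variance — the regime the headline results live in.

Residual variances follow the variance-budget convention: each phenotype's
direct inputs are treated as independent unit-variance contributors, so
ε_X ~ N(0, 1 − Var_exp − β_UX²) (making Var(X) = 1 exactly, and the true
score-on-exposure R² exactly 0.10) and ε_Y ~ N(0, 1 − β_XY² − β_UY²).
Because X and U are correlated, the realized Var(Y) is 1.048 at the
defaults, not 1.  The analysis pipeline rank-inverse-normalizes the outcome
before 2SLS — standard practice for biomarker-style outcomes — so causal
estimates are expressed per SD of the outcome.  Two consequences worth
stating plainly: the estimand on the transformed scale is β_XY/sd(Y) ≈
0.1954 rather than 0.2000, so the externally instrumented arm shows a small
apparent downward "bias" (≈ −0.004) against the nominal 0.2, and the
overlap arm's genuine overfitting bias rides on top of that (≈ +0.006 net).
These are properties of the study design being emulated, not estimator
defects; the R² quantities are unaffected.

Genotype draws use inverse-CDF sampling on 32-bit uniform integers
(probability quantization 2⁻³², i.e. exact in practice), roughly 4× faster
than a generic binomial sampler at these matrix sizes.  Dosages are used
as-is (0/1/2), never centred or standardized, matching the "weighted sum of
effect alleles" definition of the score.  All SNPs are independent — no
linkage disequilibrium — so no clumping step exists.

## Estimators

**GWAS scan.**  Per-SNP univariate OLS with intercept, computed from
column-wise sufficient statistics; two-sided P-values on the t distribution
with n−2 df (exact at the small n used in tests).  Monomorphic SNPs are
reported as beta 0, SE +∞, P 1 — they keep their row (so SNP indices never
shift) but can never be selected.

**Leave-one-block-out scans.**  Per-block column sums are subtracted from
full-cohort sums, so the jackknife's n_block discovery scans cost one extra
pass over the genotype matrix.  A consequence of the subtraction is that
per-block weights are reproducible only up to summation-order rounding
(~1e-12 relative); the two-block reduction (each half scored exactly as an
external construction from the other half) is tested at that precision.

**Selection and scoring.**  Inclusive comparison (P ≤ threshold); weight =
discovery beta; scores are not standardized (2SLS is invariant to
instrument scaling, which is also tested).  Selections at nested thresholds
are nested.

**2SLS.**  Just-identified IV with intercept (and optional covariates,
which are residualized out).  Model-based homoskedastic SE with
σ̂² = RSS/(n−k) where residuals use the *observed* exposure, y − Xβ̂ — the
convention of the standard `ivreg`-style implementations whose coverage
behaviour the study characterizes.  CIs use the normal 1.96 multiplier (n
is large in every scenario).  Robust/sandwich SEs are deliberately not
offered: the coverage results are statements about the model-based SE.

**Multivariable 2SLS.**  Two exposures, two instruments, solved from the
moment equations Z'(y − Xβ) = 0; conditional F for each exposure is the
partial F of the instrument block after accounting for the other exposure's
first-stage prediction (a Sanderson–Windmeijer-style construction; the
exact variant used in applied work is not pinned down, and none of the
simulation results depend on it).

**Rank-based inverse normal.**  Φ⁻¹((r − 3/8)/(n + 1/4)) with ties sharing
the average rank (Blom offset); a constant vector is rejected.

## Monte-Carlo metrics

`summarize_estimates` reports mean, median, bias, empirical SE (n−1
denominator), model SE (√mean(se²)), percent relative error in model SE,
MSE, coverage and bias-eliminated coverage of nominal 95% intervals, each
with its Monte Carlo standard error (MCSE), following the standard
simulation-study methodology (the algebraic identity
MSE = bias² + empSE²·(R−1)/R is tested exactly).  Replicates whose
instrument selected no SNPs are recorded as NA and excluded with a reported
count, never silently dropped.  The zipper table ranks replicates by |z| =
|β̂ − β|/SE descending and keeps the top fraction (default half) — with
fraction 1 its mean covers-flag equals the coverage metric exactly.
Precision gain is 100·((empSE_external/empSE_method)² − 1), computed when
the external arm is present in the same grid.

## Scenario runners and problem sizes

One GWAS per framework per replicate; all 13 thresholds are post-hoc
filters of that single scan, and all 13 scores come from one matrix
product.  Replicates use independent child streams spawned from one root
seed, so results are bit-reproducible and independent of worker count.

The packaged runs use reduced replicate counts chosen to keep a full
reproduction on one CPU in the tens of minutes: 200 replicates for the
primary grid and the external-size sweep, 200 for the SNP sweep in the
acceptance script (150 in the test suite), 100 for the block sweep
(the original study used 1000/1000/300/100).  At 200 replicates the MCSE of
a mean R̂² is ≈3×10⁻⁴ and of a coverage ≈1.6%; all quoted comparisons carry
these MCSEs explicitly.

## What the simulations do and do not show

The generator reproduces the mechanism of interest — winner's curse plus
sample-overlap overfitting under threshold selection — under idealized
conditions: independent common SNPs at a single allele frequency, purely
additive effects, Gaussian phenotypes, one unmeasured confounder, no
population structure, relatedness, LD, or selection into the sample.
Passing tests therefore demonstrate correctness of the estimators and of
the comparative behaviour of the three instrument-construction designs in
this regime; they say nothing about LD-induced clumping artifacts, rare
variants, binary outcomes, pleiotropy (excluded by construction), or the
mixed-model adjustments real-cohort scans require.

## Known limitations

- The jackknife implementation targets dense in-memory dosage matrices;
  50 000×2000 is comfortable (≈0.8 GB), biobank-scale data is not the aim.
- Mean bias of just-identified IV is formally undefined (no moments); at
  the instrument strengths simulated (first-stage F ≈ 10²–10³) the
  Monte-Carlo means are well behaved, but metrics at very weak thresholds
  in small custom scenarios should be read with care.
- `precision_gain_vs_external` is only defined where an external arm exists
  in the same scenario cell.
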