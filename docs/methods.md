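# Methods

## Overview

`gaintrend` implements the two-stage mixed-model analysis used to estimate
genetic trends and select elite panels from long-running multi-environment
trial series.  Stage 1 turns each year × treatment unit of plot data into
genotype BLUEs with standard errors; stage 2 fits a pedigree animal model
to the inverse-variance-weighted BLUEs and yields breeding values,
prediction error variances (PEV) and reliabilities; the trend module
regresses breeding values on year of origin.  A synthetic breeding-program
generator provides data with known truth for every stage.

## The REML engine

All models are instances of

    y = X b + sum_k Z_k u_k + e,   u_k ~ N(0, G_k s2_k),   e ~ N(0, R),

with `G_k` identity or a supplied covariance (the pedigree A-matrix) and a
diagonal `R` that is homogeneous, weighted (`phi / w_i`, known weights, one
estimated scale), or grouped-heterogeneous (one variance per group, e.g.
per treatment).  Estimation maximizes the restricted likelihood through
the mixed-model equations (MME):

* EM-REML updates for the first 5 iterations (monotone in the restricted
  log-likelihood), then average-information (AI) Newton steps.  An AI step
  that decreases the likelihood, leaves the parameter space, or yields a
  singular AI matrix falls back to EM for that iteration.  Components
  pushed below the floor by an AI step are pinned there and the step is
  re-solved for the free components (active set); without this, boundary
  fits crawl.
* Convergence: relative change of every component < 1e-6 and
  |Δ log-likelihood| < 1e-8, capped at 200 iterations; additionally, ten
  consecutive iterations with |Δ log-likelihood| < 1e-8 count as converged,
  because near-singular designs can let components wander along a flat
  ridge at no likelihood cost.
* Variance components are floored at 1e-8 × the sample phenotypic
  variance; a component ending on the floor is reported as 0 and flagged
  as a boundary estimate.
* The restricted log-likelihood is computed exactly from one Cholesky
  factor of the MME coefficient matrix (Henderson's determinant
  identities), including the `(n - p) log 2π` constant, so it is directly
  comparable with other REML software.  The engine reproduces lme4's
  log-likelihoods to ~1e-7 and variance components to ~1e-5 relative on
  frozen reference fits.
* Fixed-effect identifiability is handled by pivoted-QR column reduction;
  reported level means are estimable functions (checked against the row
  space of the full design), with other fixed factors averaged equally and
  covariates at their sample mean.  Dense linear algebra throughout; the
  largest systems fitted (stage 2) are a few thousand equations.

## Stage 1

Yield in one year × treatment unit (both seasons):
genotype fixed; replicate, incomplete block (alpha-lattice rows only) and
season random; DTF centered within the unit as a covariate on yield only.
Augmented-RCBD trials contribute their blocks as the replicate-like term
(the design has no true replication); the season term is dropped when the
unit covers a single season.  The combined analysis adds a fixed treatment
effect and a per-treatment residual variance; each genotype's adjusted mean
averages the two treatments with equal weights (configurable).

Cullis heritability is computed per trial with genotype refit as random:
`H2 = 1 - Vbar/(2 s2g)` where `Vbar` is the exact pairwise mean of
`Var(g_i - g_j)` from the full PEV block — not the common `2*mean(PEV)`
shortcut — which on balanced data reduces exactly to the classical
line-mean form `s2g r / (s2g r + s2e)` at the fitted components.  A
genetic variance on the boundary leaves `H2` undefined (reported with a
reason, never clamped).  Note that against *true* generating parameters
any plug-in heritability estimator carries a small-sample Jensen bias
(about -0.045 at 20 genotypes × 3 replicates); comparisons in the tests
are therefore against the closed form evaluated on the same data.

## Outlier QC

Whole trials are dropped for >20% missing yield, single-replicate
replicated designs, or unknown design labels.  Within a trial, conditional
residuals from the per-trial model are standardized by their estimated
variances (`R - W C^{-1} W'` diagonal at the REML estimates), converted to
leave-one-out (externally studentized) form, and tested two-sided against
a t distribution with `n - p - 1` degrees of freedom under Holm step-down.
The family is one trial by default (stage-1 models are per trial, so
residuals are only comparable within one); a dataset-wide family is a
config switch.  Removal is single-pass.

The detection model takes genotype as **random**: with genotype fixed, an
outlier on an unreplicated entry (augmented designs) is absorbed exactly
by its own genotype effect and leaves a zero residual, so it can never be
flagged; shrinkage restores the signal.  The fixed-genotype variant is
available (`genotype_random=False`).  Measured operating characteristics
on the synthetic program: family-wise error ≈ 0.045 at α = 0.05 on clean
trials; sensitivity ≈ 0.99 for 10σ contamination at 1% rate.

## Stage 2

Per context (non-stress, drought, combined), the weighted animal model
`blue = mu + g + year + e` with `g ~ N(0, A s2g)`, evaluation year an
identity random effect, and `Var(e_i) = phi * se_i^2` with one estimated
scale `phi` (the supplied weights fix only relative precisions).  `A` is
built by the tabular method over the *full* pedigree and never on a pruned
subset; its sparse inverse uses Henderson's rules with the inbreeding
(Quaas) correction, with inbreeding coefficients from the Meuwissen–Luo
recursion.  Unknown parents are unrelated non-inbred founders; with one
known parent the known side contributes alone.

Reliability is `r = 1 - PEV / s2g`, the literal definition; for inbred
individuals the textbook denominator `(1 + F) s2g` is available as
`reliability_form="inbreeding-corrected"`.  Reported reliabilities are
clipped to [0, 1] with the raw value retained alongside.  The *evaluation*
year (random effect) and a line's *year of origin* (trend metadata) are
deliberately distinct columns.

## Trend, maturity, panel, PCA

The genetic trend is unweighted OLS of EBV on year of origin; percent gain
divides the slope by the mean EBV of the regressed subset (the denominator
is not standardized in the literature; the regression prediction at the
first year is the config alternative).  The loess curve is a tricube-
weighted local quadratic on the observed year grid, span 0.75 by default,
widened with a warning when a window would hold fewer than four distinct
years.  Maturity classes from DTF breeding values: early 85–109 d, medium
110–124 d, late ≥ 125 d, with values below 85 d reported separately as
"very-early".  The core panel filters reliability > 0.4, ranks by EBV
(ties: higher reliability, then id) and takes the top 200.  The pedigree
PCA column-centers `A` (no scaling; both configurable) and reads scores
and variance fractions off the SVD.

## The synthetic generator

The generator emulates the statistical structure of a 15–17 year rice
drought-breeding series: yearly cohorts (8 crosses × 5 progeny by
default) descending from 40 founders; paired drought / non-stress trials
in two seasons per year; drought suppressing the trial mean by 60%
(within the 40–80% range such series show); a 50/30/20 mix of
alpha-lattice / RCBD / augmented designs; per-trial residual multipliers
`10^U(-1.25, 1.25)` so fitted per-trial heritabilities span roughly
0.05–0.95; DTF genotype means ~N(115 d, 9 d) acting on yield at
30 kg/ha/day so maturity confounds yield until covariate-adjusted, with
5 d of plot-level DTF noise; founders' years of origin spread over the
preceding decade.  Cohorts are trialled in their entry year and re-tested
the following year, and 8 permanent checks appear in every trial — the
across-year connectivity that lets the model separate evaluation-year
effects from the genetic trend (with single-year testing the two are
nearly confounded and the estimated trend is compressed by ~40%).

True breeding values follow the infinitesimal model (progeny = midparent
+ Mendelian deviation with variance `s2g (1 - (F_s + F_d)/2) / 2`,
inbreeding tracked by an incremental tabular kinship).  The genetic trend
is induced by selection on true BV, with three deliberate variance
reductions so that the realized trend matches the requested one tightly
(seed SD ≈ 2.5 kg/ha/yr instead of ≈ 17 under plain truncation): parents
are the contiguous rank window whose mean best matches the target
differential, parent usage across crosses is balanced round-robin, and
Mendelian deviations are centered within each cohort.  With
`selection_fraction = 1` all candidates are parents and the expected trend
is zero (a nonzero requested trend is rejected in that case).

What the generator does **not** emulate: genotype-by-environment
interaction beyond treatment-specific means and variances, spatial field
trend, marker data, selection on phenotype (selection acts on true BV, so
real-data selection bias on the trend may be larger than the sims show),
attrition/missingness patterns, and unbalanced check fractions.  Passing
the recovery tests therefore shows the estimator chain is correct under
the stated model, not that every real-data complication is handled.

## Problem sizes and numerical notes

The default program is ~640 genotypes, ~60 trials, ~12,000 plots; a full
pipeline run is ~10 s (combined context) on one core.  The acceptance
suite uses 20-seed recovery and 50-seed null calibrations at this size.
Degenerate inputs: constant responses return zero variance components and
the constant mean; trials with residual df < 3 skip outlier testing with a
warning; genotypes absent from the pedigree are fatal with the offending
list; subsetting of `A` always happens after construction on the full
pedigree (subset-then-invert ≠ invert-then-subset).
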