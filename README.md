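# gaintrend

Two-stage pedigree-BLUP analysis of multi-year, multi-environment field
trials: per-trial adjusted means, Cullis heritability, breeding values with
reliabilities, genetic-trend estimation, and elite core-panel selection.

## The problem

A breeding program accumulates years of yield trials — different field
designs (alpha-lattice, RCBD, augmented RCBD), paired stress / non-stress
managements, seasons, and a stream of new lines connected across years only
through repeated checks and the pedigree.  Two questions matter to the
program: *is the program gaining?* (the genetic trend, in kg/ha per year and
as a percentage), and *which lines should seed the next cycle?* (an elite
panel with reliable, high breeding values).  `gaintrend` answers both with
the standard two-stage mixed-model workflow used for historical rice
drought-breeding data, and ships a synthetic breeding-program generator so
every stage can be verified by parameter recovery against known truth.

## The model

**Stage 1** (per year × treatment): plot yield is modelled as

    y = mu + genotype (fixed) + replicate + block + season (random)
        + beta * DTF + e

with days-to-flowering (DTF) as a covariate deconfounding maturity from
yield.  The genotype BLUEs and standard errors feed stage 2 with weights
`w = 1/se^2`.  A combined analysis adds a fixed treatment effect with a
separate residual variance per treatment.  Per trial, with genotype refit
as random, the generalized (Cullis) line-mean heritability is

    H^2 = 1 - Vbar_BLUP / (2 sigma2_g)

where `Vbar_BLUP` is the mean variance of BLUP differences over genotype
pairs, computed exactly from the full prediction-error covariance block.

**Stage 2** (across years, per context): an animal model on the weighted
BLUEs,

    blue = mu + g + year + e,    g ~ N(0, A sigma2_g),

with `A` the pedigree numerator relationship matrix (tabular method;
Henderson's sparse inverse for the mixed-model equations) and residual
variances proportional to `se^2` times one REML-estimated scale.  Each
genotype gets an estimated breeding value `EBV = mu + g_hat`, a prediction
error variance, and a reliability `r = 1 - PEV / sigma2_g`.

**Trend and panel**: the genetic trend is the OLS regression of EBVs on
each line's *year of origin* (slope in kg/ha/yr; percent gain relative to
the subset mean EBV), with a tricube local-quadratic (loess) curve for the
non-parametric view; the core panel is the top of the EBV ranking among
genotypes with reliability > 0.4, and a PCA of `A` shows how the panel
samples the collection's diversity.

All REML fits use a purpose-built dense engine (EM start, average-
information acceleration, exact restricted likelihood via the MME
identities) validated against closed forms and an independent reference
implementation.

## A worked example

```sh
python examples/03_pedigree_blup_trend.py
```

prints (seed 42):

```
QC: 11864 plots in, 11860 retained, 4 outliers removed
stage 2: sigma2_g = 3.35e+05 (kg/ha)^2, mean reliability 0.87
corr(EBV, true BV) = 0.93
genetic trend: 22.1 +- 3.0 kg/ha/yr = 0.58%/yr of the mean breeding value (truth: 20.2 kg/ha/yr)
```

The simulated program had a realized genetic trend of 20.2 kg/ha/yr; the
pipeline, seeing only plot phenotypes and the pedigree, recovers
22.1 ± 3.0 kg/ha/yr and breeding values correlating 0.93 with the (normally
unobservable) truth.  The other examples cover the generator itself
(`01`), single-trial BLUEs and heritability (`02`), and panel selection
with pedigree PCA (`04`).

The same pipeline runs from the shell on real data:

```sh
gaintrend run --config config.yaml        # files mode: phenotypes.csv + pedigree.csv
gaintrend simulate --out demo --seed 7    # write a synthetic dataset
gaintrend trend --bv demo/bv_combined.csv
```

The phenotype CSV schema is
`trial,year,season,treatment,design,rep,block,genotype,yield_kg_ha,dtf_days,ph_cm`;
the pedigree CSV is `id,sire,dam,year_of_origin` with blank/NA for unknown
parents.

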