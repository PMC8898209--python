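"""Stage 1: per-year adjusted genotype means (BLUEs) and Cullis heritability.

For every year x treatment unit (spanning the dry- and wet-season trials),
genotype enters as a fixed effect and replications, incomplete blocks and
season as random effects; days to flowering (DTF) is a covariate for the
yield model only, absorbing maturity differences that otherwise confound
yield.  The combined analysis adds a fixed treatment effect and estimates
a separate residual variance per treatment.  Adjusted means carry their
standard errors; the weight ``1/se^2`` is what stage 2 uses to whiten the
heterogeneous precision of the per-year means.

Heritability is computed per trial (one year x season x treatment) on the
generalized line-mean scale of Cullis: ``H^2 = 1 - Vbar_blup / (2
sigma2_g)``, where ``Vbar_blup`` is the mean variance of BLUP differences
over all genotype pairs, taken from the full prediction-error covariance
block of a refit with genotype random.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from gaintrend.lmm import ModelError, ModelSpec, RandomTerm, estimate_blues, reml_fit

logger = logging.getLogger(__name__)

TRAIT_COLUMNS = {"yield": "yield_kg_ha", "dtf": "dtf_days", "ph": "ph_cm"}


@dataclass
class HeritabilityEstimate:
    trial: str
    H2: Optional[float]
    vbar_blup: Optional[float]
    sigma2_g: float
    reason: Optional[str] = None


def _design_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Per-trial replication and incomplete-block factor keys.

    Alpha-lattice trials contribute a rep term and a block-within-rep term;
    RCBD trials a rep term only; augmented-RCBD trials use their blocks as
    the replication-like term (the design has no true replication).  An
    empty key means the term does not apply to that record.
    """
    df = df.copy()
    design = df["design"]
    trial = df["trial"].astype(str)
    rep = trial + ":" + df["rep"].astype(str)
    rep = rep.where(design != "augmented_rcbd", trial + ":" + df["block"].astype(str))
    blk = (trial + ":" + df["rep"].astype(str) + ":" + df["block"].astype(str)).where(
        design == "alpha_lattice", ""
    )
    df["_rep"] = rep
    df["_blk"] = blk
    return df


def _unit_spec(
    df: pd.DataFrame,
    response: str,
    use_dtf_covariate: bool,
    combined: bool,
    genotype_random: bool = False,
) -> ModelSpec:
    fixed = [] if genotype_random else ["genotype"]
    if combined:
        fixed.append("treatment")
    random: list[RandomTerm] = [RandomTerm("genotype")] if genotype_random else []
    random.append(RandomTerm("_rep"))
    if (df["_blk"] != "").sum() > 0 and df.loc[df["_blk"] != "", "_blk"].nunique() >= 2:
        random.append(RandomTerm("_blk"))
    if df["season"].nunique() >= 2:
        random.append(RandomTerm("season"))
    else:
        logger.info("single season in unit; season term dropped")
    covs = []
    if use_dtf_covariate and response == "yield_kg_ha" and df["dtf_days"].nunique() > 1:
        covs = ["_dtf_c"]
    return ModelSpec(
        response=response,
        fixed_factors=fixed,
        covariates=covs,
        random_terms=random,
        residual="grouped" if combined else "homogeneous",
        group_col="treatment" if combined else None,
    )


def _prepare(df: pd.DataFrame) -> pd.DataFrame:
    out = _design_columns(df)
    # center DTF within the analysis unit so the intercept stays at the unit mean
    out["_dtf_c"] = out["dtf_days"] - out["dtf_days"].mean()
    return out


def fit_trial(
    pheno: pd.DataFrame,
    trait: str = "yield",
    use_dtf_covariate: bool = True,
) -> pd.DataFrame:
    """BLUEs for one year x treatment unit (both seasons).

    Returns a table ``genotype, year, context, trait, blue, se, weight``
    with ``context`` the treatment name.  The DTF covariate applies to the
    yield model only.
    """
    if pheno["treatment"].nunique() != 1 or pheno["year"].nunique() != 1:
        raise ModelError("fit_trial expects a single year x treatment unit")
    response = TRAIT_COLUMNS[trait]
    df = _prepare(pheno)
    spec = _unit_spec(df, response, use_dtf_covariate and trait == "yield", combined=False)
    if len(spec.random_terms) and df["_rep"].nunique() < 2:
        spec.random_terms = [t for t in spec.random_terms if t.factor != "_rep"]
    fit = reml_fit(spec, df)
    blues = estimate_blues(fit, "genotype")
    out = blues.rename(columns={"level": "genotype"})
    out.insert(1, "year", pheno["year"].iloc[0])
    out.insert(2, "context", pheno["treatment"].iloc[0])
    out.insert(3, "trait", trait)
    out["weight"] = 1.0 / out["se"] ** 2
    return out


def fit_combined(
    pheno: pd.DataFrame,
    trait: str = "yield",
    use_dtf_covariate: bool = True,
    treatment_weights: Optional[dict[str, float]] = None,
) -> pd.DataFrame:
    """Combined-treatment BLUEs for one year (both treatments, both seasons).

    The model adds a fixed treatment effect and a separate residual
    variance per treatment; each genotype receives one adjusted mean
    averaging the treatments with equal weights (configurable).  Genotypes
    observed under a single treatment are still reported, flagged by
    ``n_treatments``.
    """
    if pheno["year"].nunique() != 1:
        raise ModelError("fit_combined expects a single year")
    if pheno["treatment"].nunique() < 2:
        raise ModelError("fit_combined needs both treatments present")
    response = TRAIT_COLUMNS[trait]
    df = _prepare(pheno)
    spec = _unit_spec(df, response, use_dtf_covariate and trait == "yield", combined=True)
    fit = reml_fit(spec, df)
    avg = None
    if treatment_weights is not None:
        levels = fit._design.factor_levels["treatment"]
        avg = {"treatment": [treatment_weights.get(lv, 0.0) for lv in levels]}
    blues = estimate_blues(fit, "genotype", average_factors=avg)
    out = blues.rename(columns={"level": "genotype"})
    out.insert(1, "year", pheno["year"].iloc[0])
    out.insert(2, "context", "combined")
    out.insert(3, "trait", trait)
    out["weight"] = 1.0 / out["se"] ** 2
    n_trt = pheno.dropna(subset=[response]).groupby("genotype")["treatment"].nunique()
    out["n_treatments"] = out["genotype"].map(n_trt).fillna(0).astype(int)
    single = out.loc[out["n_treatments"] < 2, "genotype"]
    if len(single):
        logger.info("%d genotypes observed under a single treatment", len(single))
    return out


def trial_heritability(
    trial_df: pd.DataFrame, use_dtf_covariate: bool = True
) -> HeritabilityEstimate:
    """Cullis heritability for one trial, genotype refit as random.

    ``Vbar_blup`` is the exact pairwise mean of ``Var(g_i - g_j)`` from
    the full PEV block (not the common ``2 * mean(PEV)`` shortcut).  A
    boundary genetic variance leaves the heritability undefined.
    """
    trial = str(trial_df["trial"].iloc[0])
    df = _prepare(trial_df)
    spec = _unit_spec(
        df, "yield_kg_ha", use_dtf_covariate, combined=False, genotype_random=True
    )
    fit = reml_fit(spec, df)
    s2g = fit.varcomp["sigma2_genotype"]
    if s2g <= 0:
        return HeritabilityEstimate(trial, None, None, s2g, reason="sigma2_g at boundary")
    P = fit.pev_block("genotype")
    q = P.shape[0]
    if q < 2:
        return HeritabilityEstimate(trial, None, None, s2g, reason="fewer than 2 genotypes")
    s1 = float(np.trace(P))
    s2 = float(P.sum())
    vbar = 2.0 * (q * s1 - s2) / (q * (q - 1))
    h2 = 1.0 - vbar / (2.0 * s2g)
    if not 0.0 <= h2 <= 1.0:
        logger.warning("trial %s: H2=%.3f outside [0,1] (reported raw)", trial, h2)
    return HeritabilityEstimate(trial, float(h2), float(vbar), float(s2g))


def stage1_all_units(
    pheno: pd.DataFrame,
    traits: tuple[str, ...] = ("yield",),
    contexts: tuple[str, ...] = ("non-stress", "drought", "combined"),
    use_dtf_covariate: bool = True,
    treatment_weights: Optional[dict[str, float]] = None,
) -> pd.DataFrame:
    """Run stage 1 over every year: per-treatment and combined BLUEs."""
    frames = []
    for year, ydf in pheno.groupby("year", sort=True):
        for trait in traits:
            for trt in ("non-stress", "drought"):
                if trt not in contexts:
                    continue
                sub = ydf[ydf["treatment"] == trt]
                if sub.empty:
                    continue
                try:
                    frames.append(fit_trial(sub, trait, use_dtf_covariate))
                except ModelError as exc:
                    logger.warning("stage1 %s year=%s trait=%s failed: %s", trt, year, trait, exc)
            if "combined" in contexts and ydf["treatment"].nunique() >= 2:
                try:
                    frames.append(
                        fit_combined(ydf, trait, use_dtf_covariate, treatment_weights)
                    )
                except ModelError as exc:
                    logger.warning("stage1 combined year=%s trait=%s failed: %s", year, trait, exc)
    if not frames:
        raise ModelError("stage 1 produced no adjusted means")
    return pd.concat(frames, ignore_index=True)


def heritability_all_trials(
    pheno: pd.DataFrame, use_dtf_covariate: bool = True
) -> pd.DataFrame:
    rows = []
    for trial, tdf in pheno.groupby("trial", sort=False):
        try:
            est = trial_heritability(tdf, use_dtf_covariate)
        except ModelError as exc:
            est = HeritabilityEstimate(str(trial), None, None, np.nan, reason=str(exc))
        rows.append(
            {
                "trial": est.trial,
                "H2": est.H2,
                "vbar_blup": est.vbar_blup,
                "sigma2_g": est.sigma2_g,
                "reason": est.reason,
            }
        )
    return pd.DataFrame(rows)
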