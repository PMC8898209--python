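"""Stage 2: inverse-variance-weighted pedigree BLUP and reliabilities.

The stage-1 adjusted means (one per genotype x year within a context) are
the response of an animal model

    blue = mu + genotype + eval_year + e

with the genotype effect distributed N(0, A sigma2_g) for the pedigree
numerator relationship matrix A, the evaluation-year effect identity
random, and residual variances proportional to the squared standard
errors of the means (one common scale estimated by REML).  Every pedigree
member — including unphenotyped ancestors — receives a breeding value via
A; a genotype's reliability is ``r = 1 - PEV / sigma2_g``.

Note the two distinct year notions: the random `year` factor here is the
*evaluation* year of a trial; the *year of origin* of a line (its cohort)
is metadata joined onto the output for trend estimation downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from gaintrend.lmm import MixedModelFit, ModelSpec, RandomTerm, reml_fit
from gaintrend.pedigree import Pedigree, build_a_inverse, build_a_matrix

logger = logging.getLogger(__name__)


class Stage2Error(ValueError):
    pass


@dataclass
class PedigreeBlupResult:
    fit: MixedModelFit
    table: pd.DataFrame  # the breeding-value table
    context: str
    sigma2_g: float


def fit_pedigree_blup(
    blues: pd.DataFrame,
    ped: Pedigree,
    context: str = "combined",
    reliability_form: str = "paper",
) -> PedigreeBlupResult:
    """Weighted pedigree BLUP for one context's BLUE table.

    ``blues`` needs columns ``genotype, year, blue, se, weight``.  All
    phenotyped genotypes must be in the pedigree (fatal otherwise, with
    the offending list).  Returns the fit plus a table with one row per
    pedigree member: EBV (``mu + g_hat``, trait scale), centered BLUP,
    PEV, raw and clipped reliability, year of origin and record count.

    ``reliability_form='paper'`` divides PEV by ``sigma2_g`` as the
    reliability definition states; ``'inbreeding-corrected'`` divides by
    ``(1 + F) sigma2_g``, the textbook form for inbred individuals.
    """
    if reliability_form not in ("paper", "inbreeding-corrected"):
        raise Stage2Error(f"unknown reliability_form {reliability_form!r}")
    missing = sorted(set(blues["genotype"].astype(str)) - set(ped.ids))
    if missing:
        raise Stage2Error(f"genotypes missing from pedigree: {missing}")
    if not np.all(np.isfinite(blues["weight"])) or (blues["weight"] <= 0).any():
        raise Stage2Error("weights must be positive and finite")

    A = build_a_matrix(ped)
    Ainv = build_a_inverse(ped)
    df = blues.copy()
    df["year"] = df["year"].astype(str)
    spec = ModelSpec(
        response="blue",
        random_terms=[
            RandomTerm("genotype", covariance=A.values, cov_ids=A.ids, cov_inv=Ainv),
            RandomTerm("year"),
        ],
        residual="weighted",
        weight_col="weight",
    )
    if df["year"].nunique() < 2:
        spec.random_terms = spec.random_terms[:1]
        logger.info("stage2 %s: single evaluation year, year term dropped", context)
    fit = reml_fit(spec, df)
    s2g = fit.varcomp["sigma2_genotype"]
    if s2g <= 0:
        raise Stage2Error("genetic variance at boundary: reliability undefined")

    mu = float(fit.beta[0]) if len(fit.beta) else 0.0
    ghat = fit.u["genotype"]
    pev = fit.pev["genotype"]
    F = pd.Series(A.F)
    denom = s2g * (1.0 + F) if reliability_form == "inbreeding-corrected" else s2g
    rel_raw = 1.0 - pev / denom
    rel = rel_raw.clip(0.0, 1.0)
    n_clipped = int((rel_raw != rel).sum())
    if n_clipped:
        logger.info("stage2 %s: reliability clipped for %d genotypes", context, n_clipped)
    n_rec = df.groupby("genotype").size()
    table = pd.DataFrame(
        {
            "genotype": list(A.ids),
            "context": context,
            "ebv": mu + ghat[A.ids].to_numpy(),
            "ghat": ghat[A.ids].to_numpy(),
            "pev": pev[A.ids].to_numpy(),
            "reliability": rel[A.ids].to_numpy(),
            "reliability_raw": rel_raw[A.ids].to_numpy(),
            "year_of_origin": [ped.cohort_year.get(g, np.nan) for g in A.ids],
            "n_records": [int(n_rec.get(g, 0)) for g in A.ids],
        }
    )
    return PedigreeBlupResult(fit=fit, table=table, context=context, sigma2_g=s2g)


def compute_reliability(result: PedigreeBlupResult) -> pd.Series:
    """Reliability per genotype, ``r = 1 - PEV / sigma2_g`` (unclipped)."""
    if result.sigma2_g <= 0:
        raise Stage2Error("sigma2_g is zero: reliability undefined")
    return (1.0 - result.table.set_index("genotype")["pev"] / result.sigma2_g).rename(
        "reliability"
    )
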