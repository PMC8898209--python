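"""Trial-level quality control: filtering and outlier detection.

Whole trials are dropped when grain yield is missing for more than a
threshold fraction of plots, when a design that requires replication has a
single replicate, or when the design label is unknown.  Within each
surviving trial, outliers are flagged by externally studentized residuals
from the per-trial mixed model (genotype fixed, design effects random)
with Holm step-down control of the family-wise error rate, the family
being the trial: per-trial models make residuals comparable only within a
trial.  Flagging is single-pass (no iterative refitting).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from gaintrend.lmm import ModelError, ModelSpec, RandomTerm, reml_fit

logger = logging.getLogger(__name__)

REPLICATED_DESIGNS = {"alpha_lattice", "rcbd"}
KNOWN_DESIGNS = {"alpha_lattice", "rcbd", "augmented_rcbd"}


class QCError(ValueError):
    pass


@dataclass
class QCReport:
    trials_in: int = 0
    trials_out: int = 0
    records_in: int = 0
    records_out: int = 0
    dropped_trials: list[dict] = field(default_factory=list)
    outlier_flags: pd.DataFrame = None

    def to_dict(self) -> dict:
        d = {
            "trials_in": self.trials_in,
            "trials_out": self.trials_out,
            "records_in": self.records_in,
            "records_out": self.records_out,
            "dropped_trials": self.dropped_trials,
        }
        if self.outlier_flags is not None:
            d["n_outliers"] = int(len(self.outlier_flags))
        return d


def filter_trials(
    pheno: pd.DataFrame, missing_threshold: float = 0.20
) -> tuple[pd.DataFrame, QCReport]:
    """Drop trials failing the missingness / replication / design filters."""
    for col in ("trial", "design", "rep"):
        if col not in pheno.columns:
            raise QCError(f"phenotype table lacks required column {col!r}")
    report = QCReport(
        trials_in=pheno["trial"].nunique(), records_in=len(pheno)
    )
    keep_masks = []
    for trial, sub in pheno.groupby("trial", sort=False):
        design = sub["design"].iloc[0]
        miss = sub["yield_kg_ha"].isna().mean()
        if design not in KNOWN_DESIGNS:
            reason = "invalid_design"
        elif miss > missing_threshold:
            reason = "missing>threshold"
        elif design in REPLICATED_DESIGNS and sub["rep"].nunique() < 2:
            reason = "no_replication"
        else:
            keep_masks.append(sub.index)
            continue
        report.dropped_trials.append(
            {"trial": trial, "reason": reason, "n_records": int(len(sub))}
        )
        logger.info("qc drop trial=%s reason=%s records=%d", trial, reason, len(sub))
    if not keep_masks:
        raise QCError("no trials survive QC")
    kept = pheno.loc[np.concatenate([m.to_numpy() for m in keep_masks])]
    report.trials_out = kept["trial"].nunique()
    report.records_out = len(kept)
    return kept.reset_index(drop=True), report


def _trial_spec(design: str, use_dtf_covariate: bool) -> ModelSpec:
    random = []
    if design == "alpha_lattice":
        random = [RandomTerm("rep"), RandomTerm("_rep_block")]
    elif design == "rcbd":
        random = [RandomTerm("rep")]
    else:  # augmented_rcbd: replications equal blocks, block effect only
        random = [RandomTerm("block")]
    return ModelSpec(
        response="yield_kg_ha",
        fixed_factors=["genotype"],
        covariates=["dtf_days"] if use_dtf_covariate else [],
        random_terms=random,
    )


def _drop_degenerate_random_terms(spec: ModelSpec, data: pd.DataFrame) -> ModelSpec:
    keep = []
    for term in spec.random_terms:
        if term.cov_ids is not None or data[term.factor].nunique() >= 2:
            keep.append(term)
        else:
            logger.info("dropping random term %r (<2 levels)", term.factor)
    spec.random_terms = keep
    return spec


def fit_single_trial_model(
    trial_df: pd.DataFrame, use_dtf_covariate: bool = True, genotype_random: bool = False
):
    """Per-trial mixed model; shared by QC and stage 1."""
    df = trial_df.copy()
    df["_rep_block"] = df["rep"].astype(str) + ":" + df["block"].astype(str)
    design = df["design"].iloc[0]
    spec = _trial_spec(design, use_dtf_covariate)
    if genotype_random:
        spec.fixed_factors = []
        spec.random_terms = [RandomTerm("genotype")] + spec.random_terms
    if use_dtf_covariate and df["dtf_days"].nunique() <= 1:
        spec.covariates = []
    spec = _drop_degenerate_random_terms(spec, df)
    return reml_fit(spec, df), df


def flag_outliers(
    trial_df: pd.DataFrame,
    alpha: float = 0.05,
    use_dtf_covariate: bool = True,
    genotype_random: bool = True,
) -> pd.DataFrame:
    """Flag outlying plots of one trial by externally studentized residuals.

    Conditional residuals from the per-trial model are standardized by
    their estimated variance (at the REML variance components), converted
    to leave-one-out (externally studentized) form, and tested two-sided
    against a t reference with ``resid df - 1`` degrees of freedom under
    Holm step-down at family level ``alpha``.  Returns the flagged rows
    (original index) with the studentized residual and adjusted p-value.

    By default the detection model takes genotype as *random*: with a fixed
    genotype effect an outlier on an unreplicated entry (augmented designs)
    is absorbed exactly by its own effect and leaves a zero residual, so it
    can never be flagged; shrinkage restores the signal.  Set
    ``genotype_random=False`` to test residuals of the fixed-genotype model.
    """
    needed = ["yield_kg_ha"]
    if use_dtf_covariate and "dtf_days" in trial_df.columns:
        needed.append("dtf_days")
    sub = trial_df.dropna(subset=needed)
    fit, df = fit_single_trial_model(sub, use_dtf_covariate, genotype_random=genotype_random)
    assert fit.n_obs == len(sub), "row alignment lost in trial fit"
    n = fit.n_obs
    p = fit.beta.shape[0]
    dof = n - p
    empty = pd.DataFrame(columns=["row", "studentized", "p_adj"])
    if dof < 3:
        logger.warning(
            "trial %s: residual df=%d too small for outlier testing",
            trial_df["trial"].iloc[0], dof,
        )
        return empty

    y = df[fit.spec.response].to_numpy(dtype=float)
    W = fit._W
    theta_hat = np.concatenate([fit.beta] + [fit.u[t.factor].to_numpy() for t in fit.spec.random_terms])
    resid = y - W @ theta_hat
    # Var(conditional residual) = R P R, with P via the MME identity
    v = fit._v
    H = np.einsum("ij,jk,ik->i", W, fit._Cinv, W)
    var_e = np.maximum(v - H, 1e-12 * v.mean())
    t_int = resid / np.sqrt(var_e)
    # internal -> external studentization (exact for fixed covariance)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = (dof - 1) / np.maximum(dof - t_int**2, 1e-12)
        t_ext = t_int * np.sqrt(np.where(t_int**2 >= dof, np.inf, scale))
    pvals = 2.0 * stats.t.sf(np.abs(t_ext), dof - 1)
    pvals = np.where(np.isfinite(t_ext), pvals, 0.0)
    raw = pd.DataFrame(
        {"row": sub.index.to_numpy(), "studentized": t_ext, "p_raw": pvals}
    )
    if alpha is None:  # caller will form its own testing family
        return raw
    adj = holm_adjust(pvals)
    out = raw.assign(p_adj=adj)
    return out.loc[adj <= alpha].drop(columns="p_raw").reset_index(drop=True)


def holm_adjust(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def run_qc(
    pheno: pd.DataFrame,
    missing_threshold: float = 0.20,
    outlier_alpha: float = 0.05,
    outlier_family: str = "trial",
    use_dtf_covariate: bool = True,
) -> tuple[pd.DataFrame, QCReport]:
    """Filter trials then remove flagged outliers (single pass).

    ``outlier_family`` sets the Holm family: ``"trial"`` (default; stage-1
    models are per trial, so residuals are only comparable within one) or
    ``"global"`` (one family across all surviving trials).
    """
    if outlier_family not in ("trial", "global"):
        raise QCError(f"unknown outlier_family {outlier_family!r}")
    kept, report = filter_trials(pheno, missing_threshold)
    flags = []
    for trial, sub in kept.groupby("trial", sort=False):
        try:
            f = flag_outliers(
                sub,
                alpha=None if outlier_family == "global" else outlier_alpha,
                use_dtf_covariate=use_dtf_covariate,
            )
        except ModelError as exc:
            logger.warning("trial %s: outlier model not fittable (%s)", trial, exc)
            continue
        if len(f):
            f.insert(0, "trial", trial)
            flags.append(f)
    if outlier_family == "global" and flags:
        allp = pd.concat(flags, ignore_index=True)
        allp["p_adj"] = holm_adjust(allp["p_raw"].to_numpy())
        flags = [allp.loc[allp["p_adj"] <= outlier_alpha].drop(columns="p_raw")]
        if not len(flags[0]):
            flags = []
    flags_df = (
        pd.concat(flags, ignore_index=True)
        if flags
        else pd.DataFrame(columns=["trial", "row", "studentized", "p_adj"])
    )
    report.outlier_flags = flags_df
    clean = kept.drop(index=flags_df["row"].to_numpy()) if len(flags_df) else kept
    report.records_out = len(clean)
    logger.info("qc flagged %d outliers across %d trials", len(flags_df), report.trials_out)
    return clean.reset_index(drop=True), report
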