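"""Linear mixed-model engine: REML variance components, BLUEs, BLUPs, PEV.

The engine fits models of the form

    y = X b + sum_k Z_k u_k + e,   u_k ~ N(0, G_k s2_k),   e ~ N(0, R)

where each ``G_k`` is either an identity or a supplied covariance matrix
(the pedigree A-matrix), and the residual covariance ``R`` is diagonal:
homogeneous (``phi I``), weighted (``phi / w_i`` with known per-record
weights and one estimated scale ``phi``), or grouped-heterogeneous (one
variance per group level, e.g. per treatment).

Estimation maximizes the restricted likelihood.  Iterations start with
EM-REML updates (monotone in the restricted log-likelihood) and switch to
average-information (AI) Newton steps once stable; an AI step that lowers
the likelihood or leaves the parameter space is rejected in favour of the
EM update for that iteration.  All linear algebra is dense, sized for
per-trial and across-year fits of at most a few thousand equations; BLUPs,
their prediction error variances (PEV), and the fixed-effect covariance
come from one inverse of the mixed-model-equations coefficient matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))


class ModelError(ValueError):
    pass


@dataclass
class RandomTerm:
    """A random factor with identity or supplied covariance.

    When ``covariance`` is given, ``cov_ids`` lists the factor levels in
    matrix order; levels with no data (e.g. unphenotyped pedigree
    ancestors) still receive BLUPs.  ``cov_inv`` may be supplied to avoid
    inverting ``covariance`` (e.g. Henderson's sparse A-inverse); the log
    determinant of ``covariance`` is then derived from it.
    """

    factor: str
    covariance: Optional[np.ndarray] = None
    cov_ids: Optional[list] = None
    cov_inv: Optional[np.ndarray] = None


@dataclass
class ModelSpec:
    response: str
    fixed_factors: list[str] = field(default_factory=list)
    covariates: list[str] = field(default_factory=list)
    random_terms: list[RandomTerm] = field(default_factory=list)
    intercept: bool = True
    residual: str = "homogeneous"  # homogeneous | weighted | grouped
    weight_col: Optional[str] = None
    group_col: Optional[str] = None

    def columns(self) -> list[str]:
        cols = [self.response] + list(self.fixed_factors) + list(self.covariates)
        cols += [t.factor for t in self.random_terms]
        if self.residual == "weighted":
            cols.append(self.weight_col)
        if self.residual == "grouped":
            cols.append(self.group_col)
        return cols


@dataclass
class MixedModelFit:
    spec: ModelSpec
    beta: np.ndarray                      # estimates for kept design columns
    beta_cov: np.ndarray
    beta_labels: list[tuple[str, object]]  # (term, level-or-None) per kept column
    varcomp: dict[str, float]
    u: dict[str, pd.Series]               # BLUPs per random term
    pev: dict[str, pd.Series]             # PEV diagonal per random term
    loglik: float
    converged: bool
    n_iter: int
    n_obs: int
    n_dropped: int
    boundary: list[str]
    loglik_trace: list[float]
    _design: "_Design" = None
    _Cinv: np.ndarray = None
    _term_slices: dict = None

    def pev_block(self, term: str) -> np.ndarray:
        """Full PEV (prediction-error variance/covariance) block of a term."""
        sl = self._term_slices[term]
        return self._Cinv[sl, sl]


class _Design:
    """Fixed and random design matrices with full-rank reduction bookkeeping."""

    def __init__(self, spec: ModelSpec, data: pd.DataFrame):
        n = len(data)
        cols: list[np.ndarray] = []
        labels: list[tuple[str, object]] = []
        if spec.intercept:
            cols.append(np.ones(n))
            labels.append(("(intercept)", None))
        self.factor_levels: dict[str, list] = {}
        for f in spec.fixed_factors:
            lv = pd.Categorical(data[f].astype(str))
            levels = list(lv.categories)
            if len(levels) < 1:
                raise ModelError(f"fixed factor {f!r} has no levels")
            self.factor_levels[f] = levels
            codes = lv.codes
            for j, level in enumerate(levels):
                cols.append((codes == j).astype(float))
                labels.append((f, level))
        self.covariate_means: dict[str, float] = {}
        for c in spec.covariates:
            v = data[c].to_numpy(dtype=float)
            cols.append(v)
            labels.append((c, None))
            self.covariate_means[c] = float(v.mean())
        X = np.column_stack(cols) if cols else np.zeros((n, 0))
        self.X_full = X
        self.labels_full = labels

        # full-rank reduction by pivoted QR
        if X.shape[1]:
            _, Rq, piv = linalg.qr(X, mode="economic", pivoting=True)
            diag = np.abs(np.diag(Rq))
            tol = diag.max() * max(X.shape) * np.finfo(float).eps * 10 if diag.size else 0.0
            rank = int((diag > tol).sum())
            keep = np.sort(piv[:rank])
        else:
            keep = np.array([], dtype=int)
        self.keep = keep
        self.X = X[:, keep]
        self.labels = [labels[i] for i in keep]
        self.dropped = [labels[i] for i in sorted(set(range(X.shape[1])) - set(keep))]
        if self.dropped:
            logger.debug("dropped %d rank-deficient fixed columns: %s", len(self.dropped), self.dropped)
        # row-space basis of the full X for estimability checks (computed lazily)
        self._rowspace = None

        # random designs
        self.Z: list[np.ndarray] = []
        self.levels: list[list] = []
        for term in spec.random_terms:
            # empty-string level = term does not apply to that record (zero Z row),
            # e.g. incomplete blocks in a year unit mixing lattice and RCBD trials
            obs = data[term.factor].astype(str)
            applies = obs != ""
            if term.cov_ids is not None:
                levels = [str(g) for g in term.cov_ids]
                index = {g: j for j, g in enumerate(levels)}
                unknown = sorted(set(obs) - set(levels))
                if unknown:
                    raise ModelError(
                        f"levels of {term.factor!r} missing from supplied covariance: {unknown}"
                    )
                codes = obs.map(index).to_numpy()
            else:
                cat = pd.Categorical(obs[applies])
                levels = list(cat.categories)
                codes = np.full(n, -1)
                codes[applies.to_numpy()] = cat.codes
            if term.cov_ids is None and len(levels) < 2:
                # with a supplied covariance, information flows between levels,
                # so even a single observed level is meaningful
                raise ModelError(f"random factor {term.factor!r} needs >=2 observed levels")
            Z = np.zeros((n, len(levels)))
            rows_on = np.flatnonzero(codes >= 0)
            Z[rows_on, codes[rows_on]] = 1.0
            self.Z.append(Z)
            self.levels.append(levels)

    def rowspace(self) -> np.ndarray:
        if self._rowspace is None:
            _, s, Vt = np.linalg.svd(self.X_full, full_matrices=False)
            rank = int((s > s.max() * max(self.X_full.shape) * np.finfo(float).eps).sum()) if s.size else 0
            self._rowspace = Vt[:rank]
        return self._rowspace


def _residual_structure(spec: ModelSpec, data: pd.DataFrame):
    """Return (base per-record variance multipliers, group index arrays)."""
    n = len(data)
    if spec.residual == "homogeneous":
        return np.ones(n), None, None
    if spec.residual == "weighted":
        if not spec.weight_col:
            raise ModelError("weighted residual requires weight_col")
        w = data[spec.weight_col].to_numpy(dtype=float)
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise ModelError("weights must be positive and finite")
        return 1.0 / w, None, None
    if spec.residual == "grouped":
        if not spec.group_col:
            raise ModelError("grouped residual requires group_col")
        groups = pd.Categorical(data[spec.group_col].astype(str))
        idx = [np.flatnonzero(groups.codes == j) for j in range(len(groups.categories))]
        return np.ones(n), list(groups.categories), idx
    raise ModelError(f"unknown residual structure {spec.residual!r}")


def reml_fit(
    spec: ModelSpec,
    data: pd.DataFrame,
    max_iter: int = 200,
    tol_vc: float = 1e-6,
    tol_ll: float = 1e-8,
    n_em: int = 5,
    fixed_theta: Optional[Sequence[float]] = None,
) -> MixedModelFit:
    """Fit the mixed model by REML (EM start, average-information updates).

    Records with a missing response are dropped with a logged count.
    Variance components are floored at ``1e-8`` times the sample phenotypic
    variance; components ending at the floor are reported as boundary
    estimates.
    """
    cols = [c for c in spec.columns() if c is not None]
    missing_cols = [c for c in cols if c not in data.columns]
    if missing_cols:
        raise ModelError(f"model columns absent from data: {missing_cols}")
    mask = data[spec.response].notna()
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info("dropping %d records with missing %s", n_dropped, spec.response)
    df = data.loc[mask].reset_index(drop=True)
    incomplete = df[cols].isna().any(axis=1)
    if incomplete.any():
        logger.info("dropping %d records with missing model columns", int(incomplete.sum()))
        n_dropped += int(incomplete.sum())
        df = df.loc[~incomplete].reset_index(drop=True)
    n = len(df)
    if n < 3:
        raise ModelError(f"too few complete records to fit a model (n={n})")

    y = df[spec.response].to_numpy(dtype=float)
    des = _Design(spec, df)
    X = des.X
    p = X.shape[1]
    K = len(spec.random_terms)
    base_v, group_levels, group_idx = _residual_structure(spec, df)
    n_resid = len(group_levels) if group_levels is not None else 1

    vary = float(np.var(y, ddof=1)) if n > 1 else 0.0
    if vary <= 0:
        # degenerate: constant response
        return _degenerate_fit(spec, des, df, y, n_dropped)
    floor = 1e-8 * vary

    # inverse covariances and log-dets per random term
    Ginv: list[Optional[np.ndarray]] = []
    logdetG: list[float] = []
    Gmat: list[Optional[np.ndarray]] = []
    for term, levels in zip(spec.random_terms, des.levels):
        if term.covariance is None and term.cov_inv is None:
            Ginv.append(None)  # identity
            logdetG.append(0.0)
            Gmat.append(None)
        else:
            if term.cov_inv is not None:
                Gi = np.asarray(term.cov_inv.toarray() if hasattr(term.cov_inv, "toarray") else term.cov_inv, dtype=float)
                sign, ld = np.linalg.slogdet(Gi)
                if sign <= 0:
                    raise ModelError(f"covariance inverse for {term.factor!r} not positive definite")
                logdetG.append(-ld)
                Ginv.append(Gi)
                Gmat.append(np.asarray(term.covariance, dtype=float) if term.covariance is not None else None)
            else:
                G = np.asarray(term.covariance, dtype=float)
                c, low = linalg.cho_factor(G + 1e-10 * np.eye(len(G)))
                logdetG.append(2.0 * float(np.sum(np.log(np.diag(c)))))
                Ginv.append(linalg.cho_solve((c, low), np.eye(len(G))))
                Gmat.append(G)

    W = np.column_stack([X] + des.Z) if K else X
    m = W.shape[1]
    q = [Z.shape[1] for Z in des.Z]
    slices = []
    off = p
    for qk in q:
        slices.append(slice(off, off + qk))
        off += qk

    # initial values: split phenotypic variance equally
    theta = np.full(K + n_resid, vary / (K + 1), dtype=float)
    theta[K:] = vary / (K + 1) if K else vary
    if spec.residual == "weighted":
        # scale start by mean weight so phi * base_v has the right magnitude
        theta[K] = vary / (K + 1) / float(np.mean(base_v))

    def assemble(th):
        """Build MME pieces at parameter vector th; return dict of results."""
        v = np.empty(n)
        if group_idx is not None:
            for g, idx in enumerate(group_idx):
                v[idx] = th[K + g]
        else:
            v[:] = th[K] * base_v
        Rinv = 1.0 / v
        WtRi = W.T * Rinv
        C = WtRi @ W
        for k in range(K):
            sl = slices[k]
            if Ginv[k] is None:
                C[sl, sl][np.diag_indices(q[k])] += 1.0 / th[k]
            else:
                C[sl, sl] += Ginv[k] / th[k]
        rhs = WtRi @ y
        try:
            cf = linalg.cho_factor(C)
        except linalg.LinAlgError:
            C = C + 1e-8 * np.eye(m) * np.trace(C) / m
            cf = linalg.cho_factor(C)
        sol = linalg.cho_solve(cf, rhs)
        yPy = float(y @ (Rinv * y) - rhs @ sol)
        logdetC = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        m2ll = (
            float(np.sum(np.log(v)))
            + sum(q[k] * np.log(th[k]) + logdetG[k] for k in range(K))
            + logdetC
            + yPy
            + (n - p) * _LOG2PI
        )
        return {"v": v, "Rinv": Rinv, "cf": cf, "sol": sol, "ll": -0.5 * m2ll, "C": C}

    def em_update(th, st):
        Cinv = linalg.cho_solve(st["cf"], np.eye(m))
        new = th.copy()
        tr_k = np.empty(K)
        for k in range(K):
            sl = slices[k]
            uk = st["sol"][sl]
            Ck = Cinv[sl, sl]
            if Ginv[k] is None:
                quad = float(uk @ uk)
                tr = float(np.trace(Ck))
            else:
                quad = float(uk @ Ginv[k] @ uk)
                tr = float(np.sum(Ginv[k] * Ck.T))
            tr_k[k] = tr
            new[k] = max((quad + tr) / q[k], floor)
        e = y - W @ st["sol"]
        if group_idx is not None:
            H = np.einsum("ij,jk,ik->i", W, Cinv, W)
            for g, idx in enumerate(group_idx):
                new[K + g] = max((float(e[idx] @ e[idx]) + float(H[idx].sum())) / len(idx), floor)
        else:
            # tr(diag(1/base_v) W Cinv W') = phi * (m - sum_k tr(Gk^-1 Ckk)/s2_k)
            wts = 1.0 / base_v
            tr_wc = th[K] * (m - sum(tr_k[k] / th[k] for k in range(K)))
            new[K] = max((float(e @ (wts * e)) + tr_wc) / n, floor)
        return new

    def ai_update(th, st):
        Rinv = st["Rinv"]
        Py = Rinv * (y - W @ st["sol"])
        nparam = K + n_resid
        S = np.empty((n, nparam))
        for k in range(K):
            Zk = des.Z[k]
            t = Zk.T @ Py
            if Gmat[k] is not None:
                t = Gmat[k] @ t
            elif Ginv[k] is not None:
                t = np.linalg.solve(Ginv[k], t)
            S[:, k] = Zk @ t
        if group_idx is not None:
            for g, idx in enumerate(group_idx):
                col = np.zeros(n)
                col[idx] = Py[idx]
                S[:, K + g] = col
        else:
            S[:, K] = base_v * Py
        # P S = Rinv (S - W C^-1 W' Rinv S)
        RS = Rinv[:, None] * S
        PS = Rinv[:, None] * (S - W @ linalg.cho_solve(st["cf"], W.T @ RS))
        AI = 0.5 * (S.T @ PS)
        # scores
        Cinv = linalg.cho_solve(st["cf"], np.eye(m))
        score = np.empty(nparam)
        tr_k = np.empty(K)
        for k in range(K):
            sl = slices[k]
            Ck = Cinv[sl, sl]
            tr = float(np.trace(Ck)) if Ginv[k] is None else float(np.sum(Ginv[k] * Ck.T))
            tr_k[k] = tr
            trPV = q[k] / th[k] - tr / th[k] ** 2
            score[k] = -0.5 * (trPV - float(Py @ S[:, k]))
        if group_idx is not None:
            H = np.einsum("ij,jk,ik->i", W, Cinv, W)
            for g, idx in enumerate(group_idx):
                trPD = float(np.sum(1.0 / st["v"][idx])) - float(np.sum(H[idx] / st["v"][idx] ** 2))
                score[K + g] = -0.5 * (trPD - float(Py @ S[:, K + g]))
        else:
            trPV_rand = sum(th[k] * (q[k] / th[k] - tr_k[k] / th[k] ** 2) for k in range(K))
            trPD = ((n - p) - trPV_rand) / th[K]
            score[K] = -0.5 * (trPD - float(Py @ S[:, K]))
        # active-set Newton step: components pushed below the floor are pinned
        # there and the step is re-solved for the remaining free components
        free = np.ones(nparam, dtype=bool)
        new = th.copy()
        for _ in range(nparam):
            sub = AI[np.ix_(free, free)] + 1e-12 * np.eye(int(free.sum()))
            try:
                step = np.linalg.solve(sub, score[free])
            except np.linalg.LinAlgError:
                return None
            new = th.copy()
            new[free] = th[free] + step
            new[~free] = floor
            viol = (new < floor) & free
            if not viol.any():
                break
            free &= ~viol
            if not free.any():
                break
        if np.any(~np.isfinite(new)):
            return None
        return np.maximum(new, floor)

    if fixed_theta is not None:
        theta = np.asarray(fixed_theta, dtype=float)
        if theta.shape != (K + n_resid,):
            raise ModelError(
                f"fixed_theta needs {K + n_resid} components "
                f"({K} random terms + {n_resid} residual)"
            )
        max_iter = 0

    st = assemble(theta)
    trace = [st["ll"]]
    converged = fixed_theta is not None
    it = 0
    rel = np.inf
    plateau = 0
    for it in range(1, max_iter + 1):
        proposal = None
        if it > n_em:
            cand = ai_update(theta, st)
            if cand is not None:
                st_cand = assemble(cand)
                if np.isfinite(st_cand["ll"]) and st_cand["ll"] >= st["ll"] - 1e-10:
                    proposal = (cand, st_cand)
        if proposal is None:
            cand = em_update(theta, st)
            st_cand = assemble(cand)
            proposal = (cand, st_cand)
        new_theta, new_st = proposal
        rel = np.max(np.abs(new_theta - theta) / np.maximum(np.abs(theta), floor))
        dll = abs(new_st["ll"] - st["ll"])
        theta, st = new_theta, new_st
        trace.append(st["ll"])
        if dll < tol_ll:
            plateau += 1
        else:
            plateau = 0
        if rel < tol_vc and dll < tol_ll:
            converged = True
            break
        # flat likelihood ridge: components may wander at no likelihood cost
        if plateau >= 10:
            converged = True
            break
    if not converged:
        logger.warning("REML did not converge in %d iterations (last rel change %.2e)", it, rel)

    # final quantities
    Cinv = linalg.cho_solve(st["cf"], np.eye(m))
    sol = st["sol"]
    beta = sol[:p]
    beta_cov = Cinv[:p, :p]
    u: dict[str, pd.Series] = {}
    pev: dict[str, pd.Series] = {}
    term_slices: dict[str, slice] = {}
    varcomp: dict[str, float] = {}
    boundary: list[str] = []
    for k, term in enumerate(spec.random_terms):
        sl = slices[k]
        u[term.factor] = pd.Series(sol[sl], index=des.levels[k])
        pev[term.factor] = pd.Series(np.diag(Cinv[sl, sl]), index=des.levels[k])
        term_slices[term.factor] = sl
        varcomp[f"sigma2_{term.factor}"] = float(theta[k])
    if group_idx is not None:
        for g, lev in enumerate(group_levels):
            varcomp[f"sigma2_e[{lev}]"] = float(theta[K + g])
    else:
        varcomp["sigma2_e"] = float(theta[K])
    for name in list(varcomp):
        if varcomp[name] <= floor * (1 + 1e-9):
            boundary.append(name)
            varcomp[name] = 0.0

    fit = MixedModelFit(
        spec=spec,
        beta=beta,
        beta_cov=beta_cov,
        beta_labels=des.labels,
        varcomp=varcomp,
        u=u,
        pev=pev,
        loglik=float(st["ll"]),
        converged=converged,
        n_iter=it,
        n_obs=n,
        n_dropped=n_dropped,
        boundary=boundary,
        loglik_trace=trace,
        _design=des,
        _Cinv=Cinv,
        _term_slices=term_slices,
    )
    fit._data = df
    fit._W = W
    fit._theta = theta
    fit._v = st["v"]
    return fit


def _degenerate_fit(spec, des, df, y, n_dropped):
    p = des.X.shape[1]
    beta = np.zeros(p)
    if p:
        beta, *_ = np.linalg.lstsq(des.X, y, rcond=None)
    varcomp = {f"sigma2_{t.factor}": 0.0 for t in spec.random_terms}
    varcomp["sigma2_e"] = 0.0
    u = {t.factor: pd.Series(0.0, index=des.levels[k]) for k, t in enumerate(spec.random_terms)}
    pev = {t.factor: pd.Series(0.0, index=des.levels[k]) for k, t in enumerate(spec.random_terms)}
    fit = MixedModelFit(
        spec=spec,
        beta=beta,
        beta_cov=np.zeros((p, p)),
        beta_labels=des.labels,
        varcomp=varcomp,
        u=u,
        pev=pev,
        loglik=np.nan,
        converged=True,
        n_iter=0,
        n_obs=len(y),
        n_dropped=n_dropped,
        boundary=sorted(varcomp),
        loglik_trace=[],
        _design=des,
        _Cinv=np.zeros((p, p)),
        _term_slices={t.factor: slice(0, 0) for t in spec.random_terms},
    )
    fit._data = df
    return fit


def estimate_blues(
    fit: MixedModelFit,
    factor: str,
    average_factors: Optional[dict[str, Sequence[float]]] = None,
) -> pd.DataFrame:
    """Estimable level means (intercept + effect) with GLS standard errors.

    Other fixed factors are averaged with equal weights over their levels
    (override per-factor weights via ``average_factors``); covariates are
    evaluated at their sample mean.  Non-estimable levels are excluded and
    reported in the ``estimable`` column of the log.
    """
    des = fit._design
    if factor not in des.factor_levels:
        raise ModelError(f"{factor!r} is not a fixed factor of the model")
    labels_full = des.labels_full
    P = len(labels_full)
    col_of = {lab: j for j, lab in enumerate(labels_full)}
    rowspace = des.rowspace()
    keep_pos = {int(j): k for k, j in enumerate(des.keep)}

    rows = []
    for level in des.factor_levels[factor]:
        L = np.zeros(P)
        if ("(intercept)", None) in col_of:
            L[col_of[("(intercept)", None)]] = 1.0
        L[col_of[(factor, level)]] = 1.0
        for other, levels in des.factor_levels.items():
            if other == factor:
                continue
            if average_factors and other in average_factors:
                wts = np.asarray(average_factors[other], dtype=float)
                wts = wts / wts.sum()
            else:
                wts = np.full(len(levels), 1.0 / len(levels))
            for wl, lv in zip(wts, levels):
                L[col_of[(other, lv)]] = wl
        for cov, mean in des.covariate_means.items():
            L[col_of[(cov, None)]] = mean
        # estimability: L must lie in the row space of the full design
        proj = rowspace.T @ (rowspace @ L)
        estimable = bool(np.allclose(proj, L, atol=1e-8 * max(1.0, np.abs(L).max())))
        Lk = np.array([L[j] for j in des.keep])
        est = float(Lk @ fit.beta)
        se = float(np.sqrt(max(Lk @ fit.beta_cov @ Lk, 0.0)))
        rows.append({"level": level, "blue": est, "se": se, "estimable": estimable})
    out = pd.DataFrame(rows)
    dropped = out.loc[~out["estimable"], "level"].tolist()
    if dropped:
        logger.info("non-estimable levels of %s excluded: %s", factor, dropped)
    return out.loc[out["estimable"]].drop(columns="estimable").reset_index(drop=True)


def predict_blups(fit: MixedModelFit, term: str) -> pd.DataFrame:
    """BLUPs with prediction-error variances for one random term."""
    if term not in fit.u:
        raise ModelError(f"{term!r} is not a random term of the model")
    return pd.DataFrame({"blup": fit.u[term], "pev": fit.pev[term]})
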