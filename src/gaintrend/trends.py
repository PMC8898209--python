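"""Genetic trends, loess curves, maturity classes, core panel, pedigree PCA.

The genetic trend of a breeding program is the regression of estimated
breeding values on each line's year of origin; the slope is the annual
genetic gain (kg/ha per year) and the percent gain expresses it relative
to a baseline yield.  A loess curve over the same scatter shows short- and
long-term changes that a single slope hides.  The elite core panel is the
top of the breeding-value ranking among genotypes whose reliability
exceeds a threshold, and a principal component analysis of the pedigree
relationship matrix summarizes how well the selected panel spans the
diversity of the whole collection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from gaintrend.pedigree import RelationshipMatrix

logger = logging.getLogger(__name__)


class TrendError(ValueError):
    pass


@dataclass
class TrendEstimate:
    context: str
    subset: str
    slope: float          # kg/ha per year
    slope_se: float
    percent_gain: float   # % per year
    baseline: float       # denominator of percent_gain
    n: int
    r2: float
    intercept: float

    def to_dict(self) -> dict:
        return {
            "context": self.context,
            "subset": self.subset,
            "slope": self.slope,
            "slope_se": self.slope_se,
            "percent_gain": self.percent_gain,
            "baseline": self.baseline,
            "n": self.n,
            "r2": self.r2,
            "intercept": self.intercept,
        }


@dataclass
class PanelSelection:
    selected: list[str]
    n_target: int
    reliability_min: float
    ebv_min: Optional[float]
    pc_scores: Optional[pd.DataFrame] = None

    def to_dict(self) -> dict:
        return {
            "selected": list(self.selected),
            "n_target": self.n_target,
            "reliability_min": self.reliability_min,
            "ebv_min": self.ebv_min,
        }


def estimate_genetic_trend(
    bv: pd.DataFrame,
    subset: str = "all-genotypes",
    subset_ids: Optional[set] = None,
    baseline: str = "subset_mean",
) -> TrendEstimate:
    """OLS regression of EBV on year of origin.

    ``bv`` needs ``genotype, ebv, year_of_origin`` (and ``context``).
    ``baseline`` is the percent-gain denominator: the mean EBV of the
    regressed subset (default) or the regression prediction at the first
    year (``first_year_prediction``).
    """
    df = bv.dropna(subset=["ebv", "year_of_origin"])
    if subset_ids is not None:
        df = df[df["genotype"].isin(subset_ids)]
    if len(df) < 3:
        raise TrendError(f"subset {subset!r}: need >=3 genotypes with year of origin")
    x = df["year_of_origin"].to_numpy(dtype=float)
    y = df["ebv"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise TrendError("all genotypes share one year of origin: no trend estimable")
    res = stats.linregress(x, y)
    if baseline == "subset_mean":
        base = float(y.mean())
    elif baseline == "first_year_prediction":
        base = float(res.intercept + res.slope * x.min())
    else:
        raise TrendError(f"unknown baseline rule {baseline!r}")
    context = str(df["context"].iloc[0]) if "context" in df.columns else ""
    return TrendEstimate(
        context=context,
        subset=subset,
        slope=float(res.slope),
        slope_se=float(res.stderr),
        percent_gain=float(100.0 * res.slope / base),
        baseline=base,
        n=int(len(df)),
        r2=float(res.rvalue**2),
        intercept=float(res.intercept),
    )


def loess_trend(
    bv: pd.DataFrame, span: float = 0.75, degree: int = 2
) -> pd.DataFrame:
    """Tricube-weighted local polynomial regression of EBV on year of origin.

    Evaluated on the observed year grid.  A span too small to hold
    ``degree + 2`` distinct x values in each neighbourhood is widened with
    a warning.
    """
    df = bv.dropna(subset=["ebv", "year_of_origin"])
    x = df["year_of_origin"].to_numpy(dtype=float)
    y = df["ebv"].to_numpy(dtype=float)
    grid = np.unique(x)
    if len(grid) < 10:
        raise TrendError("loess trend needs >=10 distinct years")
    n = len(x)
    k = int(np.ceil(span * n))
    kmin = degree + 2
    # ensure each window spans enough distinct years
    while k < n:
        ok = all(
            len(np.unique(x[np.argsort(np.abs(x - x0))[:k]])) >= kmin for x0 in grid
        )
        if ok:
            break
        k += max(1, n // 20)
    if k > int(np.ceil(span * n)):
        logger.warning("loess span %.2f too small; widened to %.2f", span, k / n)
    k = min(k, n)
    out = np.empty(len(grid))
    for i, x0 in enumerate(grid):
        d = np.abs(x - x0)
        h = np.sort(d)[k - 1]
        if h == 0:
            h = max(d.max(), 1.0) * 1e-9
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        sel = w > 0
        X = np.vander(x[sel] - x0, degree + 1, increasing=True)
        Wh = w[sel]
        XtW = X.T * Wh
        coef, *_ = np.linalg.lstsq(XtW @ X, XtW @ y[sel], rcond=None)
        out[i] = coef[0]
    return pd.DataFrame({"year_of_origin": grid, "ebv_smooth": out})


MATURITY_BINS = {
    "very-early": (-np.inf, 85.0),
    "early": (85.0, 110.0),
    "medium": (110.0, 125.0),
    "late": (125.0, np.inf),
}


def classify_maturity(dtf: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Maturity class per genotype from DTF breeding values.

    Early 85-109 d, medium 110-124 d, late >= 125 d; values below 85 d
    fall outside the published bins and are reported separately as
    ``very-early``.  Returns (classes, class percentages).
    """
    v = dtf.astype(float)
    classes = pd.Series(
        pd.cut(
            v,
            bins=[-np.inf, 85.0, 110.0, 125.0, np.inf],
            labels=["very-early", "early", "medium", "late"],
            right=False,
        ),
        index=dtf.index,
        name="maturity",
    )
    pct = classes.value_counts(normalize=True).sort_index() * 100.0
    return classes, pct


def select_core_panel(
    bv: pd.DataFrame, n_target: int = 200, reliability_min: float = 0.4
) -> PanelSelection:
    """Top-``n_target`` genotypes by EBV among those with reliability above
    the threshold; ties broken by higher reliability, then id."""
    df = bv.dropna(subset=["ebv", "reliability"]).copy()
    eligible = df[df["reliability"] > reliability_min]
    if eligible.empty:
        logger.warning("no genotype exceeds reliability %.2f: empty panel", reliability_min)
        return PanelSelection([], n_target, reliability_min, None)
    ranked = eligible.sort_values(
        ["ebv", "reliability", "genotype"], ascending=[False, False, True]
    )
    if len(ranked) < n_target:
        logger.warning(
            "only %d eligible genotypes for a target of %d", len(ranked), n_target
        )
    sel = ranked.head(n_target)
    return PanelSelection(
        selected=sel["genotype"].tolist(),
        n_target=n_target,
        reliability_min=reliability_min,
        ebv_min=float(sel["ebv"].min()),
    )


def pedigree_pca(
    A: RelationshipMatrix,
    selected: Optional[set] = None,
    k: int = 2,
    center: bool = True,
    scale: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the pedigree relationship matrix.

    Each genotype's row of A (its relationship profile) is the feature
    vector; columns are centered (optionally scaled) and the principal
    axes come from the singular value decomposition.  Returns the score
    table (with a ``selected`` mask if given) and the variance-explained
    fractions.
    """
    M = A.values.astype(float).copy()
    if center:
        M -= M.mean(axis=0, keepdims=True)
    if scale:
        sd = M.std(axis=0, keepdims=True)
        sd[sd == 0] = 1.0
        M /= sd
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    rank = int((s > s.max() * 1e-12).sum()) if s.size else 0
    if k > rank:
        logger.warning("requested %d components but rank is %d; truncating", k, rank)
        k = rank
    scores = U[:, :k] * s[:k]
    varexp = s**2 / np.sum(s**2) if s.size else np.array([])
    out = pd.DataFrame(
        scores, columns=[f"pc{i + 1}" for i in range(k)], index=A.ids
    ).rename_axis("genotype").reset_index()
    if selected is not None:
        out["selected"] = out["genotype"].isin(selected)
    return out, varexp[:k]
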