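"""Synthetic breeding programs and multi-environment trial data with known truth.

The generator emulates the statistical structure of a multi-year rice
drought-breeding program: cohorts of lines entering over many years with a
positive additive genetic trend, long-term checks creating across-year
connectivity, paired drought / non-stress trials in two seasons per year
with drought suppressing the trial mean, a mix of alpha-lattice / RCBD /
augmented-RCBD designs, per-trial residual variances spanning a wide
heritability range, and days-to-flowering (DTF) variation that confounds
yield unless adjusted by a covariate.

True breeding values follow the infinitesimal model: a progeny's BV is the
parent average plus a Mendelian-sampling deviation with variance
``sigma2_g * (1 - (F_sire + F_dam)/2) / 2``.  The genetic trend is induced
by truncation-window selection of parents on true BV: each year the parent
set is the contiguous rank window (of size ``selection_fraction`` times the
candidate cohort) whose mean best matches the previous cohort mean plus
``true_trend``, so the requested trend is achieved in expectation while
selection still acts on true breeding values.  With
``selection_fraction = 1`` every candidate is a parent and the expected
trend is zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from gaintrend.pedigree import Pedigree, load_and_sort_pedigree

DESIGNS = ("alpha_lattice", "rcbd", "augmented_rcbd")


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of the synthetic breeding program.

    Yield is in kg/ha; variances in (kg/ha)^2.  Defaults describe a
    15-year program with a true genetic trend of 20 kg/ha per year,
    additive variance 4e5, paired drought / non-stress trials with drought
    suppressing the trial mean by 60%, and per-trial residual variances
    drawn log-uniformly around the treatment base so that per-trial
    heritabilities span roughly 0.2–0.95.
    """

    n_founders: int = 40
    n_years: int = 15
    crosses_per_year: int = 8
    progeny_per_cross: int = 5
    selection_fraction: float = 0.2
    true_trend: float = 20.0
    sigma2_g: float = 4.0e5
    sigma2_e_ns: float = 4.0e5
    sigma2_e_dr: float = 6.0e5
    drought_mean_reduction: float = 0.6
    n_checks: int = 8
    dtf_effect: float = 30.0
    design_mix: tuple[float, float, float] = (0.5, 0.3, 0.2)  # alpha, rcbd, augmented
    seed: int = 1
    # environmental structure
    base_yield: float = 5000.0
    sigma2_rep: float = 2.0e4
    sigma2_block: float = 4.0e4
    sigma2_season: float = 5.0e4
    sigma2_year: float = 5.0e4
    resid_log10_spread: float = 1.25  # per-trial residual multiplier in 10^+-spread
    founder_year_span: int = 10  # founders (checks) originate over the preceding decade
    dtf_mean: float = 115.0
    dtf_sd_genetic: float = 9.0  # genotype DTF means span ~85-135 d; medium class dominates
    dtf_sd_plot: float = 5.0
    ph_mean: float = 100.0
    ph_sd_genetic: float = 12.0
    ph_sd_plot: float = 5.0
    n_reps_alpha: int = 2
    n_reps_rcbd: int = 3

    def validate(self) -> None:
        counts = {
            "n_founders": self.n_founders,
            "n_years": self.n_years,
            "crosses_per_year": self.crosses_per_year,
            "progeny_per_cross": self.progeny_per_cross,
            "n_checks": self.n_checks,
        }
        for name, v in counts.items():
            if v < 1:
                raise SimConfigError(f"{name} must be >= 1, got {v}")
        if self.sigma2_g <= 0:
            raise SimConfigError("sigma2_g must be > 0")
        for name in ("sigma2_e_ns", "sigma2_e_dr", "sigma2_rep",
                     "sigma2_block", "sigma2_season", "sigma2_year"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        if not 0 < self.selection_fraction <= 1:
            raise SimConfigError("selection_fraction must be in (0, 1]")
        if not 0 <= self.drought_mean_reduction < 1:
            raise SimConfigError("drought_mean_reduction must be in [0, 1)")
        cohort = self.crosses_per_year * self.progeny_per_cross
        if self.selection_fraction * cohort < 1:
            raise SimConfigError("selection_fraction * cohort size must be >= 1")
        n_par = max(2, int(np.ceil(self.selection_fraction * cohort)))
        if self.selection_fraction < 1 and n_par < 2:
            raise SimConfigError("selection cannot supply two distinct parents per cross")
        if self.true_trend != 0 and self.selection_fraction >= 1:
            raise SimConfigError(
                "a nonzero true_trend requires selection_fraction < 1 "
                "(with every candidate a parent there is no selection differential)"
            )
        if abs(sum(self.design_mix) - 1.0) > 1e-8 or min(self.design_mix) < 0:
            raise SimConfigError("design_mix must be non-negative and sum to 1")
        if self.n_checks > self.n_founders:
            raise SimConfigError("n_checks cannot exceed n_founders")


@dataclass
class SyntheticDataset:
    pedigree: Pedigree
    true_bv: dict[str, float]
    cohort_year: dict[str, float]
    checks: list[str]
    phenotypes: Optional[pd.DataFrame] = None
    truth: dict = field(default_factory=dict)


def simulate_breeding_program(config: SimConfig) -> SyntheticDataset:
    """Simulate the pedigree and true breeding values (no phenotypes yet)."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    sg = np.sqrt(config.sigma2_g)

    ids: list[str] = []
    sires: list[Optional[str]] = []
    dams: list[Optional[str]] = []
    bv: list[float] = []
    year: list[float] = []
    # dense kinship table grown incrementally (tabular recursion)
    cap = config.n_founders + config.n_years * config.crosses_per_year * config.progeny_per_cross
    A = np.zeros((cap, cap))
    idx: dict[str, int] = {}

    def add(ind, sire, dam, value, yr):
        i = len(ids)
        ids.append(ind)
        sires.append(sire)
        dams.append(dam)
        bv.append(value)
        year.append(yr)
        idx[ind] = i
        if sire is None and dam is None:
            A[i, i] = 1.0
        else:
            s, d = idx[sire], idx[dam]
            A[i, :i] = 0.5 * (A[s, :i] + A[d, :i])
            A[:i, i] = A[i, :i]
            A[i, i] = 1.0 + 0.5 * A[s, d]

    # founders originate over the preceding years (ascending, so the pedigree
    # stays ordered by cohort); their mean BV follows the same trend line so
    # the check series carries the program's history
    n_f = config.n_founders
    span = config.founder_year_span
    f_years = [
        float(-span + round(span * f / (n_f - 1))) if n_f > 1 else 0.0
        for f in range(n_f)
    ]
    for f in range(n_f):
        mean = config.true_trend * f_years[f]
        add(f"F{f:03d}", None, None, float(rng.normal(mean, sg)), f_years[f])
    # checks spread across the founder year range
    check_idx = np.unique(np.linspace(0, n_f - 1, config.n_checks).round().astype(int))
    checks = [f"F{f:03d}" for f in check_idx]

    cohort = list(ids)  # year-0 candidates = founders
    cohort_means = []
    for t in range(1, config.n_years + 1):
        cand = sorted(cohort, key=lambda g: bv[idx[g]])
        n_cand = len(cand)
        if config.selection_fraction >= 1:
            parents = list(cand)
        else:
            n_par = max(2, int(np.ceil(config.selection_fraction * n_cand)))
            # absolute target: cohort means track the line true_trend * year
            target = config.true_trend * t
            vals = np.array([bv[idx[g]] for g in cand])
            window_means = np.convolve(vals, np.ones(n_par) / n_par, mode="valid")
            j = int(np.argmin(np.abs(window_means - target)))
            parents = cand[j : j + n_par]
        # balanced round-robin pairing over a shuffled parent list keeps the
        # average midparent equal to the parent-set mean, and Mendelian
        # deviations are centered within the cohort: both are variance
        # reductions so the realized trend tracks the requested one tightly
        order = list(parents)
        rng.shuffle(order)
        n_par = len(order)
        crosses = []
        for c in range(config.crosses_per_year):
            sire = order[c % n_par]
            dam = order[(c + 1) % n_par]
            crosses.append((sire, dam))
        n_prog = config.crosses_per_year * config.progeny_per_cross
        z = rng.standard_normal(n_prog)
        z -= z.mean()
        new_cohort = []
        k = 0
        for c, (sire, dam) in enumerate(crosses):
            Fs = A[idx[sire], idx[sire]] - 1.0
            Fd = A[idx[dam], idx[dam]] - 1.0
            ms_sd = np.sqrt(max(config.sigma2_g * (1.0 - 0.5 * (Fs + Fd)) / 2.0, 0.0))
            mid = 0.5 * (bv[idx[sire]] + bv[idx[dam]])
            for p in range(config.progeny_per_cross):
                ind = f"Y{t:02d}C{c:02d}P{p:02d}"
                add(ind, sire, dam, float(mid + ms_sd * z[k]), float(t))
                new_cohort.append(ind)
                k += 1
        cohort = new_cohort
        cohort_means.append(float(np.mean([bv[idx[g]] for g in cohort])))

    ped = load_and_sort_pedigree(
        list(zip(ids, sires, dams)), {g: year[idx[g]] for g in ids}
    )
    yrs = np.arange(1, len(cohort_means) + 1, dtype=float)
    realized = float(np.polyfit(yrs, cohort_means, 1)[0]) if len(yrs) > 1 else 0.0
    truth = {
        "config": asdict(config),
        "cohort_means": cohort_means,
        "realized_trend": realized,
    }
    return SyntheticDataset(
        pedigree=ped,
        true_bv={g: bv[idx[g]] for g in ids},
        cohort_year={g: year[idx[g]] for g in ids},
        checks=checks,
        truth=truth,
    )


def _make_plots(rng, design, entries, checks, config):
    """Return (genotype, rep, block) plot rows for one trial."""
    rows = []
    if design == "alpha_lattice":
        n_blk = max(2, int(np.ceil(np.sqrt(len(entries)))))
        for r in range(1, config.n_reps_alpha + 1):
            perm = list(entries)
            rng.shuffle(perm)
            for b, chunk in enumerate(np.array_split(perm, n_blk), start=1):
                rows += [(g, f"R{r}", f"B{b}") for g in chunk]
    elif design == "rcbd":
        for r in range(1, config.n_reps_rcbd + 1):
            rows += [(g, f"R{r}", f"R{r}") for g in entries]
    else:  # augmented_rcbd: checks in every block, test entries once
        tests = [g for g in entries if g not in checks]
        n_blk = max(2, int(np.ceil(len(tests) / 10)))
        perm = list(tests)
        rng.shuffle(perm)
        for b, chunk in enumerate(np.array_split(perm, n_blk), start=1):
            for g in list(chunk) + list(checks):
                rows.append((g, "R1", f"B{b}"))
    return rows


def simulate_trials(dataset: SyntheticDataset, config: SimConfig) -> pd.DataFrame:
    """Simulate plot-level phenotypes for every year x treatment x season trial.

    Plot yield = trial mean + true BV + rep + block + season + year effects
    + dtf_effect * (plot DTF - population mean DTF) + residual.  Drought
    trials have their trial mean scaled by ``1 - drought_mean_reduction``
    and use the drought residual base variance.  Each trial draws a
    log-uniform residual-variance multiplier so realized heritabilities
    spread widely.  The result is stored on ``dataset.phenotypes`` and
    returned.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    ids = dataset.pedigree.ids
    n_id = len(ids)
    dtf_geno = dict(zip(ids, config.dtf_mean + config.dtf_sd_genetic * rng.standard_normal(n_id)))
    ph_geno = dict(zip(ids, config.ph_mean + config.ph_sd_genetic * rng.standard_normal(n_id)))
    year_eff = {t: rng.normal(0.0, np.sqrt(config.sigma2_year)) for t in range(1, config.n_years + 1)}

    records = []
    h2_truth = {}
    for t in range(1, config.n_years + 1):
        # a cohort is trialled in its entry year and re-tested the following
        # year: repeated testing of lines across successive years (plus the
        # permanent checks) is what connects the year series
        entries = [g for g, yr in dataset.cohort_year.items() if yr in (t, t - 1) and yr > 0]
        entries = sorted(entries) + dataset.checks
        for treatment in ("non-stress", "drought"):
            base_e = config.sigma2_e_ns if treatment == "non-stress" else config.sigma2_e_dr
            mean_scale = 1.0 if treatment == "non-stress" else 1.0 - config.drought_mean_reduction
            for season in ("dry", "wet"):
                trial = f"Y{t:02d}_{season}_{'ns' if treatment == 'non-stress' else 'dr'}"
                trng = np.random.default_rng(
                    np.random.SeedSequence([config.seed, 303, t,
                                            0 if treatment == "non-stress" else 1,
                                            0 if season == "dry" else 1])
                )
                design = DESIGNS[trng.choice(3, p=list(config.design_mix))]
                mult = 10.0 ** trng.uniform(-config.resid_log10_spread, config.resid_log10_spread)
                sig_e = base_e * mult
                plots = _make_plots(trng, design, entries, dataset.checks, config)
                season_eff = trng.normal(0.0, np.sqrt(config.sigma2_season))
                reps = sorted({r for _, r, _ in plots})
                blocks = sorted({(r, b) for _, r, b in plots})
                rep_eff = {r: trng.normal(0.0, np.sqrt(config.sigma2_rep)) for r in reps}
                blk_eff = {rb: trng.normal(0.0, np.sqrt(config.sigma2_block)) for rb in blocks}
                trial_mean = config.base_yield * mean_scale + year_eff[t] + season_eff
                n_reps_eff = len(reps) if design != "augmented_rcbd" else 1
                h2_truth[trial] = config.sigma2_g / (config.sigma2_g + sig_e / max(n_reps_eff, 1))
                for g, r, b in plots:
                    dtf = dtf_geno[g] + trng.normal(0.0, config.dtf_sd_plot)
                    ph = ph_geno[g] - (15.0 if treatment == "drought" else 0.0) + trng.normal(
                        0.0, config.ph_sd_plot
                    )
                    y = (
                        trial_mean
                        + dataset.true_bv[g]
                        + rep_eff[r]
                        + blk_eff[(r, b)]
                        + config.dtf_effect * (dtf - config.dtf_mean)
                        + trng.normal(0.0, np.sqrt(sig_e))
                    )
                    records.append(
                        (trial, t, season, treatment, design, r, b, g, y, dtf, ph)
                    )
    pheno = pd.DataFrame(
        records,
        columns=[
            "trial", "year", "season", "treatment", "design", "rep", "block",
            "genotype", "yield_kg_ha", "dtf_days", "ph_cm",
        ],
    )
    dataset.phenotypes = pheno
    dataset.truth["h2_plot_basis"] = h2_truth
    return pheno


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """Full simulation: pedigree + true BVs + plot phenotypes."""
    ds = simulate_breeding_program(config)
    simulate_trials(ds, config)
    return ds


def inject_outliers(
    table: pd.DataFrame, rate: float, magnitude: float, seed: int
) -> tuple[pd.DataFrame, pd.Series]:
    """Shift a random fraction of plots by +-magnitude residual SDs.

    The per-trial residual SD is estimated as the SD of within-genotype
    yield deviations.  Returns the contaminated copy and a boolean truth
    flag per row.  Rates above 5% are rejected: heavier contamination
    breaks the stage-1 model assumptions the flagging test relies on.
    """
    if not 0 <= rate <= 0.05:
        raise SimConfigError("outlier rate must be in [0, 0.05]")
    out = table.copy()
    flags = pd.Series(False, index=out.index)
    if rate == 0 or len(out) == 0:
        return out, flags
    rng = np.random.default_rng(seed)
    n_out = int(round(rate * len(out)))
    if n_out == 0:
        return out, flags
    chosen = rng.choice(out.index.to_numpy(), size=n_out, replace=False)
    # pooled within-genotype SD per trial, replicated entries only: the SD of
    # deviations over singletons (augmented test entries) is identically zero
    # and would deflate the estimate
    grp = out.groupby(["trial", "genotype"])["yield_kg_ha"]
    dev = out["yield_kg_ha"] - grp.transform("mean")
    size = grp.transform("size")
    repl = out.loc[size >= 2].assign(dev2=dev[size >= 2] ** 2, dof=1.0 - 1.0 / size[size >= 2])
    agg = repl.groupby("trial").agg(ss=("dev2", "sum"), dof=("dof", "sum"))
    resid_sd = np.sqrt(agg["ss"] / agg["dof"]).reindex(
        out["trial"].unique()
    ).fillna(out["yield_kg_ha"].std())
    signs = rng.choice([-1.0, 1.0], size=n_out)
    for row, s in zip(chosen, signs):
        sd = resid_sd[out.at[row, "trial"]]
        if not np.isfinite(sd) or sd == 0:
            sd = float(out["yield_kg_ha"].std())
        out.at[row, "yield_kg_ha"] = out.at[row, "yield_kg_ha"] + s * magnitude * sd
    flags.loc[chosen] = True
    return out, flags


def write_truth_json(dataset: SyntheticDataset, path) -> None:
    payload = dict(dataset.truth)
    payload["true_bv"] = dataset.true_bv
    payload["cohort_year"] = dataset.cohort_year
    payload["checks"] = dataset.checks
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
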