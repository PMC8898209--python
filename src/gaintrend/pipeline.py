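"""End-to-end driver: simulate/load -> QC -> stage 1 -> stage 2 -> trends/panel.

Artifacts are written under the configured output directory:

    phenotypes.csv, pedigree.csv, truth.json    (simulate mode)
    qc_report.json
    blues.csv, h2_trials.csv
    bv_<context>.csv
    trends.json, loess_<context>.csv
    maturity.csv
    panel.json, pca_scores.csv
    plots/trend_<context>.png, plots/pca_biplot.png
    manifest.json

The manifest echoes the configuration, the package version, per-stage
record counts, convergence flags, and wall-clock times; counts reconcile
across stages.  All randomness flows from the single config seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

import gaintrend
from gaintrend import io as gio
from gaintrend.lmm import ModelError
from gaintrend.pedigree import Pedigree, build_a_matrix, read_pedigree_csv, write_pedigree_csv
from gaintrend.qc import run_qc
from gaintrend.simdata import SimConfig, simulate_dataset, write_truth_json
from gaintrend.stage1 import heritability_all_trials, stage1_all_units
from gaintrend.stage2 import Stage2Error, fit_pedigree_blup
from gaintrend.trends import (
    TrendError,
    classify_maturity,
    estimate_genetic_trend,
    loess_trend,
    pedigree_pca,
    select_core_panel,
)

logger = logging.getLogger(__name__)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: gio.PipelineConfig, make_plots: bool = True) -> dict:
    """Run the full analysis; returns a dict of in-memory results + manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": gaintrend.__version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "stages": {},
        "status": "running",
    }
    results: dict = {"manifest": manifest}

    def stage(name):
        manifest["stages"][name] = {"t_start": time.time()}
        return manifest["stages"][name]

    def done(rec, **counts):
        rec["wall_clock_s"] = round(time.time() - rec.pop("t_start"), 3)
        rec.update(counts)

    try:
        # ---- input ----------------------------------------------------
        rec = stage("input")
        checks: list[str] = []
        if config.mode == "simulate":
            sim_cfg = SimConfig(**{**config.sim, "seed": config.seed})
            ds = simulate_dataset(sim_cfg)
            pheno, ped = ds.phenotypes, ds.pedigree
            checks = ds.checks
            gio.write_phenotypes(pheno, out / "phenotypes.csv")
            write_pedigree_csv(ped, out / "pedigree.csv")
            write_truth_json(ds, out / "truth.json")
            results["truth"] = ds
        else:
            pheno = gio.read_phenotypes(config.phenotypes)
            ped = read_pedigree_csv(config.pedigree)
            if config.checks:
                checks = [
                    line.strip()
                    for line in Path(config.checks).read_text().splitlines()
                    if line.strip()
                ]
        done(rec, records_in=len(pheno), trials_in=int(pheno["trial"].nunique()),
             pedigree_size=len(ped), n_checks=len(checks))

        # ---- QC -------------------------------------------------------
        rec = stage("qc")
        clean, qc_report = run_qc(
            pheno,
            missing_threshold=config.qc["missing_threshold"],
            outlier_alpha=config.qc["outlier_alpha"],
            outlier_family=config.qc.get("outlier_family", "trial"),
            use_dtf_covariate=config.stage1["use_dtf_covariate"],
        )
        (out / "qc_report.json").write_text(
            json.dumps(qc_report.to_dict(), indent=1, default=_json_default)
        )
        done(rec, records_in=len(pheno), records_out=len(clean),
             outliers_removed=int(len(qc_report.outlier_flags)),
             trials_dropped=len(qc_report.dropped_trials))
        results["qc_report"] = qc_report
        results["phenotypes_clean"] = clean

        # ---- stage 1 ---------------------------------------------------
        rec = stage("stage1")
        contexts = tuple(config.stage2["contexts"])
        traits = tuple(config.stage1.get("traits", ("yield",)))
        weights = config.stage1.get("combined_weights")
        blues = stage1_all_units(
            clean,
            traits=traits,
            contexts=contexts,
            use_dtf_covariate=config.stage1["use_dtf_covariate"],
            treatment_weights=weights,
        )
        gio.write_blues(blues, out / "blues.csv")
        h2 = heritability_all_trials(clean, config.stage1["use_dtf_covariate"])
        h2.to_csv(out / "h2_trials.csv", index=False, float_format="%.6g")
        done(rec, records_in=len(clean), blues_out=len(blues),
             h2_defined=int(h2["H2"].notna().sum()), h2_trials=len(h2))
        results["blues"] = blues
        results["h2"] = h2

        # ---- stage 2 ---------------------------------------------------
        rec = stage("stage2")
        bv_tables: dict[str, pd.DataFrame] = {}
        fits = {}
        converged = {}
        for ctx in contexts:
            sub = blues[(blues["context"] == ctx) & (blues["trait"] == "yield")]
            if sub.empty:
                continue
            res = fit_pedigree_blup(
                sub, ped, context=ctx,
                reliability_form=config.stage2["reliability_form"],
            )
            bv_tables[ctx] = res.table
            fits[ctx] = res
            converged[ctx] = bool(res.fit.converged)
            cols = ["genotype", "context", "ebv", "ghat", "pev", "reliability",
                    "year_of_origin", "n_records"]
            res.table[cols].to_csv(
                out / f"bv_{ctx.replace('-', '_')}.csv", index=False, float_format="%.15g"
            )
        done(rec, contexts=list(bv_tables), converged=converged,
             records_in=int((blues["trait"] == "yield").sum()),
             genotypes_out={c: len(t) for c, t in bv_tables.items()})
        results["bv"] = bv_tables
        results["stage2_fits"] = fits

        # maturity classes from DTF breeding values (combined context)
        if "dtf" in traits and "combined" in contexts:
            dtf_blues = blues[(blues["context"] == "combined") & (blues["trait"] == "dtf")]
            if len(dtf_blues):
                try:
                    dtf_res = fit_pedigree_blup(dtf_blues, ped, context="combined")
                    tb = dtf_res.table.set_index("genotype")
                    phen = tb[tb["n_records"] > 0]
                    classes, pct = classify_maturity(phen["ebv"])
                    mat = phen.assign(maturity=classes)[["ebv", "maturity"]]
                    mat.to_csv(out / "maturity.csv", float_format="%.6g")
                    results["maturity"] = mat
                    results["maturity_pct"] = pct
                except (Stage2Error, ModelError) as exc:
                    logger.warning("maturity classification skipped: %s", exc)

        # ---- trends ----------------------------------------------------
        rec = stage("trends")
        trend_list = []
        baseline = config.trends["percent_gain_baseline"]
        span = config.trends["loess_span"]
        for ctx, table in bv_tables.items():
            phen = table[table["n_records"] > 0]
            subsets = {"all-genotypes": None}
            if checks:
                subsets["checks-and-released"] = set(checks)
            for name, ids in subsets.items():
                try:
                    tr = estimate_genetic_trend(phen, subset=name, subset_ids=ids, baseline=baseline)
                    trend_list.append(tr)
                except TrendError as exc:
                    logger.warning("trend %s/%s not estimable: %s", ctx, name, exc)
            try:
                lo = loess_trend(phen, span=span)
                lo.to_csv(out / f"loess_{ctx.replace('-', '_')}.csv", index=False,
                          float_format="%.6g")
            except TrendError as exc:
                logger.info("loess for %s skipped: %s", ctx, exc)
        (out / "trends.json").write_text(
            json.dumps([t.to_dict() for t in trend_list], indent=1, default=_json_default)
        )
        done(rec, n_trends=len(trend_list))
        results["trends"] = trend_list

        # ---- panel -----------------------------------------------------
        rec = stage("panel")
        panel = None
        if "combined" in bv_tables:
            phen = bv_tables["combined"][bv_tables["combined"]["n_records"] > 0]
            panel = select_core_panel(
                phen,
                n_target=config.panel["n_target"],
                reliability_min=config.panel["reliability_min"],
            )
            A = build_a_matrix(ped, ids=phen["genotype"].tolist())
            scores, varexp = pedigree_pca(A, selected=set(panel.selected))
            scores.to_csv(out / "pca_scores.csv", index=False, float_format="%.6g")
            pj = panel.to_dict()
            pj["pca_variance_explained"] = varexp
            (out / "panel.json").write_text(json.dumps(pj, indent=1, default=_json_default))
            results["panel"] = panel
            results["pca_scores"] = scores
            if make_plots:
                _plots(out, bv_tables, trend_list, scores)
        done(rec, n_selected=0 if panel is None else len(panel.selected))

        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = f"failed: {type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=_json_default))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=_json_default))
    return results


def _plots(out: Path, bv_tables, trend_list, pca_scores) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plots = out / "plots"
    plots.mkdir(exist_ok=True)
    for ctx, table in bv_tables.items():
        phen = table[(table["n_records"] > 0) & table["year_of_origin"].notna()]
        if phen.empty:
            continue
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.scatter(phen["year_of_origin"], phen["ebv"], s=8, alpha=0.4, color="gray")
        for tr in trend_list:
            if tr.context == ctx and tr.subset == "all-genotypes":
                xs = np.array(sorted(phen["year_of_origin"].unique()))
                ax.plot(xs, tr.intercept + tr.slope * xs, "r-",
                        label=f"{tr.slope:.1f} kg/ha/yr ({tr.percent_gain:.2f}%/yr)")
        ax.set_xlabel("year of origin")
        ax.set_ylabel("breeding value (kg/ha)")
        ax.set_title(f"genetic trend, {ctx}")
        ax.legend()
        fig.tight_layout()
        fig.savefig(plots / f"trend_{ctx.replace('-', '_')}.png", dpi=120)
        plt.close(fig)
    if pca_scores is not None and {"pc1", "pc2"} <= set(pca_scores.columns):
        fig, ax = plt.subplots(figsize=(5, 5))
        unsel = pca_scores[~pca_scores["selected"]]
        sel = pca_scores[pca_scores["selected"]]
        ax.scatter(unsel["pc1"], unsel["pc2"], s=8, color="lightgray", label="collection")
        ax.scatter(sel["pc1"], sel["pc2"], s=10, color="darkred", label="core panel")
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.legend()
        fig.tight_layout()
        fig.savefig(plots / "pca_biplot.png", dpi=120)
        plt.close(fig)
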