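"""Stage 2: weighted pedigree BLUP, reliabilities, and their limits."""

import numpy as np
import pandas as pd
import pytest

from gaintrend.lmm import ModelSpec, RandomTerm, reml_fit
from gaintrend.pedigree import build_a_inverse, build_a_matrix, load_and_sort_pedigree
from gaintrend.qc import run_qc
from gaintrend.simdata import SimConfig, simulate_dataset
from gaintrend.stage1 import stage1_all_units
from gaintrend.stage2 import Stage2Error, compute_reliability, fit_pedigree_blup


def identity_blues(seed, q=30, n_years=2, se=1.0):
    """BLUE table over unrelated founders (A = I)."""
    rng = np.random.default_rng(seed)
    ids = [f"g{i:02d}" for i in range(q)]
    rows = []
    u = rng.normal(0, 2.0, q)
    for yr in range(1, n_years + 1):
        for i, g in enumerate(ids):
            rows.append(
                {
                    "genotype": g,
                    "year": yr,
                    "blue": 10 + u[i] + rng.normal(0, se),
                    "se": se,
                    "weight": 1.0 / se**2,
                }
            )
    ped = load_and_sort_pedigree([(g, None, None) for g in ids], {g: 0 for g in ids})
    return pd.DataFrame(rows), ped


class TestPedigreeBlup:
    def test_identity_single_record_shrinkage(self):
        """A = I, equal weights, one record each: ghat is the shrunken
        centered BLUE with factor s2g / (s2g + s2e)."""
        blues, ped = identity_blues(0, n_years=1)
        res = fit_pedigree_blup(blues, ped)
        th = res.fit._theta
        k = th[0] / (th[0] + th[-1])  # single year: year term dropped
        mu = res.fit.beta[0]
        tb = res.table.set_index("genotype")
        y = blues.set_index("genotype")["blue"]
        np.testing.assert_allclose(tb.loc[y.index, "ghat"], k * (y - mu), atol=1e-8)

    def test_unphenotyped_full_sib_gets_half(self):
        """With unphenotyped founder parents, a phenotyped line's full sib
        receives exactly half its BLUP through the A-matrix."""
        ped = load_and_sort_pedigree(
            [("S", None, None), ("D", None, None), ("A", "S", "D"), ("B", "S", "D")]
        )
        rng = np.random.default_rng(1)
        blues = pd.DataFrame(
            {
                "genotype": ["A"] * 4,
                "year": [1, 1, 2, 2],
                "blue": 3.0 + rng.normal(0, 0.5, 4),
                "se": 0.5,
                "weight": 4.0,
            }
        )
        res = fit_pedigree_blup(blues, ped)
        tb = res.table.set_index("genotype")
        assert tb.loc["B", "ghat"] == pytest.approx(0.5 * tb.loc["A", "ghat"], rel=1e-8)

        # dense MME oracle at the converged components
        A = build_a_matrix(ped)
        th = res.fit._theta
        s2g, scale = th[0], th[-1]
        Z = np.zeros((4, 4))
        gidx = {g: j for j, g in enumerate(A.ids)}
        Z[:, gidx["A"]] = 1.0
        X = np.ones((4, 1))
        Ri = np.diag(blues["weight"].to_numpy() / scale)
        Ainv = np.linalg.inv(A.values)
        C = np.block([[X.T @ Ri @ X, X.T @ Ri @ Z], [Z.T @ Ri @ X, Z.T @ Ri @ Z + Ainv / s2g]])
        rhs = np.concatenate([X.T @ Ri @ blues["blue"], Z.T @ Ri @ blues["blue"]])
        sol = np.linalg.solve(C, rhs)
        np.testing.assert_allclose(
            tb.loc[list(A.ids), "ghat"], sol[1:], atol=1e-8
        )

    def test_missing_genotype_fatal_with_list(self):
        blues, ped = identity_blues(2)
        blues.loc[0, "genotype"] = "phantom"
        with pytest.raises(Stage2Error, match="phantom"):
            fit_pedigree_blup(blues, ped)

    def test_weight_rescaling_leaves_ebv_invariant(self):
        """Halving all squared SEs (doubling weights) only rescales the
        estimated residual scale; EBVs are unchanged."""
        blues, ped = identity_blues(3)
        res1 = fit_pedigree_blup(blues, ped)
        blues2 = blues.assign(weight=blues["weight"] * 2, se=blues["se"] / np.sqrt(2))
        res2 = fit_pedigree_blup(blues2, ped)
        np.testing.assert_allclose(res1.table["ebv"], res2.table["ebv"], atol=1e-6)

    def test_recovers_true_breeding_values_on_default_program(self):
        """EBVs from the full pipeline track true BVs: high correlation and
        a calibration slope near 1 (regression of truth on EBV)."""
        from scipy import stats

        corrs, slopes = [], []
        for seed in range(3):
            ds = simulate_dataset(SimConfig(seed=seed))
            clean, _ = run_qc(ds.phenotypes)
            blues = stage1_all_units(clean, contexts=("combined",))
            res = fit_pedigree_blup(blues[blues.context == "combined"], ds.pedigree)
            tb = res.table.set_index("genotype")
            truth = pd.Series(ds.true_bv)
            obs = tb[tb.n_records > 0]
            corrs.append(np.corrcoef(obs["ebv"], truth[obs.index])[0, 1])
            slopes.append(stats.linregress(obs["ebv"], truth[obs.index]).slope)
        assert min(corrs) >= 0.7
        assert 0.85 <= np.mean(slopes) <= 1.15

    def test_normal_equations_satisfied(self):
        blues, ped = identity_blues(4, q=20, n_years=3)
        res = fit_pedigree_blup(blues, ped)
        fit = res.fit
        W = fit._W
        v = fit._v
        y = fit._data["blue"].to_numpy(dtype=float)
        th = fit._theta
        C = (W.T * (1.0 / v)) @ W
        q = len(ped)
        C[1 : 1 + q, 1 : 1 + q] += np.eye(q) / th[0]
        yrs = fit.u["year"].shape[0]
        C[1 + q : 1 + q + yrs, 1 + q : 1 + q + yrs] += np.eye(yrs) / th[1]
        sol = np.concatenate(
            [fit.beta, fit.u["genotype"].to_numpy(), fit.u["year"].to_numpy()]
        )
        rhs = W.T @ (y / v)
        resid = np.abs(C @ sol - rhs).max() / max(np.abs(rhs).max(), 1.0)
        assert resid < 1e-8


class TestReliability:
    def test_prior_limits(self):
        """No information: r -> 0; near-complete information: r -> 1."""
        rng = np.random.default_rng(5)
        ids = [f"g{i}" for i in range(30)] + ["lonely"]
        ped = load_and_sort_pedigree([(g, None, None) for g in ids], {g: 0 for g in ids})
        effects = rng.normal(0, 2.0, 30)
        rows = []
        for i, g in enumerate(ids[:30]):
            for rec in range(50):  # many precise records
                rows.append(
                    {"genotype": g, "year": 1 + rec % 2,
                     "blue": effects[i] + rng.normal(0, 0.05),
                     "se": 0.05, "weight": 400.0}
                )
        res = fit_pedigree_blup(pd.DataFrame(rows), ped)
        tb = res.table.set_index("genotype")
        assert tb.loc["lonely", "reliability"] == pytest.approx(0.0, abs=1e-6)
        assert tb.loc["g0", "reliability"] > 0.95

    def test_monotone_in_record_count(self):
        """More records, higher reliability, in every replicate."""
        for seed in range(3):
            rng = np.random.default_rng(seed)
            ids = [f"g{i:02d}" for i in range(24)]
            ped = load_and_sort_pedigree([(g, None, None) for g in ids], {g: 0 for g in ids})
            effects = rng.normal(0, 2.0, len(ids))
            rows = []
            for i, g in enumerate(ids):
                n_rec = 6 if i < 12 else 1
                for r in range(n_rec):
                    rows.append(
                        {"genotype": g, "year": 1 + r % 3,
                         "blue": 5 + effects[i] + rng.normal(0, 1),
                         "se": 1.0, "weight": 1.0}
                    )
            res = fit_pedigree_blup(pd.DataFrame(rows), ped)
            tb = res.table.set_index("genotype")
            r6 = tb.loc[[g for i, g in enumerate(ids) if i < 12], "reliability"]
            r1 = tb.loc[[g for i, g in enumerate(ids) if i >= 12], "reliability"]
            assert r6.min() > r1.max()

    def test_compute_reliability_matches_table(self):
        blues, ped = identity_blues(6)
        res = fit_pedigree_blup(blues, ped)
        r = compute_reliability(res)
        tb = res.table.set_index("genotype")
        np.testing.assert_allclose(r[tb.index], tb["reliability_raw"], atol=1e-12)

    def test_inbreeding_corrected_form_lower_for_inbred(self):
        ped = load_and_sort_pedigree(
            [("P", None, None), ("Q", None, None), ("X", "P", "Q"), ("Z", "X", "X")]
        )
        rng = np.random.default_rng(7)
        eff = dict(zip(["P", "Q", "X", "Z"], rng.normal(0, 2.0, 4)))
        genos = ["P", "Q", "X", "Z"] * 3
        blues = pd.DataFrame(
            {"genotype": genos,
             "year": np.repeat([1, 2, 3], 4),
             "blue": [eff[g] + rng.normal(0, 0.5) for g in genos],
             "se": 0.5, "weight": 4.0}
        )
        paper = fit_pedigree_blup(blues, ped, reliability_form="paper").table.set_index("genotype")
        corr = fit_pedigree_blup(blues, ped, reliability_form="inbreeding-corrected").table.set_index("genotype")
        # Z is inbred (F=0.5): the corrected denominator is larger
        assert corr.loc["Z", "reliability_raw"] > paper.loc["Z", "reliability_raw"]


class TestTwoStageVsSingleStage:
    def test_high_correlation_on_balanced_homogeneous_data(self):
        """On balanced, homogeneous-variance data, the two-stage EBVs agree
        with a single-stage plot-level pedigree fit (r > 0.99)."""
        cfg = SimConfig(
            seed=3, n_years=6, resid_log10_spread=0.0, sigma2_e_dr=4e5,
            design_mix=(0.0, 1.0, 0.0), drought_mean_reduction=0.0, dtf_effect=0.0,
        )
        ds = simulate_dataset(cfg)
        ph = ds.phenotypes
        blues = stage1_all_units(ph, contexts=("combined",), use_dtf_covariate=False)
        res2 = fit_pedigree_blup(blues[blues.context == "combined"], ds.pedigree)

        A = build_a_matrix(ds.pedigree)
        Ainv = build_a_inverse(ds.pedigree)
        df = ph.copy()
        df["yr"] = df["year"].astype(str)
        df["_rep"] = df["trial"].astype(str) + ":" + df["rep"].astype(str)
        spec = ModelSpec(
            response="yield_kg_ha",
            fixed_factors=["treatment"],
            random_terms=[
                RandomTerm("genotype", covariance=A.values, cov_ids=A.ids, cov_inv=Ainv),
                RandomTerm("yr"),
                RandomTerm("trial"),
                RandomTerm("_rep"),
                RandomTerm("season"),
            ],
        )
        fit1 = reml_fit(spec, df)
        tb = res2.table.set_index("genotype")
        phenotyped = tb.index[tb["n_records"] > 0]
        r = np.corrcoef(fit1.u["genotype"][phenotyped], tb.loc[phenotyped, "ghat"])[0, 1]
        assert r > 0.99
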