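"""REML engine: closed-form oracles, GLS/dense-MME oracles, reference fits."""

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from gaintrend.lmm import ModelError, ModelSpec, RandomTerm, estimate_blues, predict_blups, reml_fit
from gaintrend.pedigree import build_a_inverse, build_a_matrix, load_and_sort_pedigree
from conftest import make_lmm_dataset, random_pedigree_trios

DATA = Path(__file__).parent / "data"


def oneway_dataset(seed, n_groups=20, n_rep=5, s2g=4.0, s2e=1.0):
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(n_groups), n_rep)
    u = rng.normal(0, np.sqrt(s2g), n_groups)
    y = 10 + u[g] + rng.normal(0, np.sqrt(s2e), n_groups * n_rep)
    return pd.DataFrame({"y": y, "g": [f"g{i:02d}" for i in g]})


class TestRemlOracles:
    @pytest.mark.parametrize("seed", range(4))
    def test_balanced_oneway_matches_anova(self, seed):
        """REML on a balanced one-way random model equals the ANOVA estimators."""
        df = oneway_dataset(seed)
        fit = reml_fit(ModelSpec(response="y", random_terms=[RandomTerm("g")]), df)
        ybar = df.groupby("g")["y"].mean()
        n_rep = 5
        msb = n_rep * ybar.var(ddof=1)
        msw = ((df["y"] - ybar[df["g"]].to_numpy()) ** 2).sum() / (len(df) - 20)
        assert fit.varcomp["sigma2_g"] == pytest.approx((msb - msw) / n_rep, abs=1e-6)
        assert fit.varcomp["sigma2_e"] == pytest.approx(msw, abs=1e-6)
        assert fit.converged

    def test_loglik_monotone_across_iterations(self):
        for seed in range(6):
            df = make_lmm_dataset(seed)
            fit = reml_fit(
                ModelSpec(
                    response="y",
                    fixed_factors=["geno"],
                    covariates=["x"],
                    random_terms=[RandomTerm("rep"), RandomTerm("block")],
                ),
                df,
            )
            trace = np.array(fit.loglik_trace)
            assert np.all(np.diff(trace) >= -1e-8)

    def test_constant_response_hits_lower_bound(self):
        df = pd.DataFrame({"y": 3.5, "g": [f"g{i}" for i in range(10)] * 2})
        fit = reml_fit(ModelSpec(response="y", random_terms=[RandomTerm("g")]), df)
        assert fit.varcomp["sigma2_g"] == 0.0
        assert fit.varcomp["sigma2_e"] == 0.0
        assert fit.beta[0] == pytest.approx(3.5)

    def test_matches_frozen_lme4_reference(self):
        """Engine agrees with an independent REML implementation (reference
        fits computed once and frozen) on loglik and variance components."""
        ref = json.loads((DATA / "lme4_reference.json").read_text())
        spec = ModelSpec(
            response="y",
            fixed_factors=["geno"],
            covariates=["x"],
            random_terms=[RandomTerm("rep"), RandomTerm("block")],
        )
        for seed in range(10):
            fit = reml_fit(spec, make_lmm_dataset(seed))
            r = ref[f"seed{seed}"]
            assert fit.loglik == pytest.approx(r["loglik"], abs=5e-5)
            for ours, theirs in [
                (fit.varcomp["sigma2_rep"], r["sigma2_rep"]),
                (fit.varcomp["sigma2_block"], r["sigma2_block"]),
                (fit.varcomp["sigma2_e"], r["sigma2_e"]),
            ]:
                assert ours == pytest.approx(theirs, rel=1e-4, abs=1e-4)

    def test_missing_response_rows_dropped(self):
        df = oneway_dataset(0)
        df.loc[::7, "y"] = np.nan
        fit = reml_fit(ModelSpec(response="y", random_terms=[RandomTerm("g")]), df)
        assert fit.n_obs == df["y"].notna().sum()
        assert fit.n_dropped == df["y"].isna().sum()

    def test_singular_fixed_design_reduced(self):
        """Rank-deficient fixed designs are reduced by pivoting; estimable
        level means are pivot-invariant and non-estimable ones excluded."""
        df = oneway_dataset(1)
        df["z"] = 1.0  # covariate aliased with the intercept
        fit = reml_fit(
            ModelSpec(response="y", fixed_factors=["g"], covariates=["z"]), df
        )
        assert len(fit._design.dropped) > 0
        blues = estimate_blues(fit, "g")
        means = df.groupby("g")["y"].mean()
        np.testing.assert_allclose(blues["blue"].to_numpy(), means.to_numpy(), atol=1e-8)

        # a fully aliased second factor makes the equal-average level mean
        # non-estimable: every level must be excluded, none silently wrong
        df2 = oneway_dataset(1)
        df2["dup"] = df2["g"]
        fit2 = reml_fit(ModelSpec(response="y", fixed_factors=["g", "dup"]), df2)
        assert estimate_blues(fit2, "g").empty


class TestBlues:
    def test_ols_limit_equals_group_means(self):
        df = oneway_dataset(2)
        fit = reml_fit(ModelSpec(response="y", fixed_factors=["g"]), df)
        blues = estimate_blues(fit, "g")
        means = df.groupby("g")["y"].mean()
        np.testing.assert_allclose(blues["blue"].to_numpy(), means.to_numpy(), atol=1e-8)
        s = np.sqrt(fit.varcomp["sigma2_e"])
        np.testing.assert_allclose(blues["se"].to_numpy(), s / np.sqrt(5), atol=1e-8)

    def test_weighted_one_group_se_closed_form(self):
        rng = np.random.default_rng(5)
        w = rng.uniform(0.5, 2.0, 40)
        y = 5 + rng.normal(0, np.sqrt(2.0 / w))
        df = pd.DataFrame({"y": y, "w": w, "grp": "all"})
        fit = reml_fit(
            ModelSpec(response="y", fixed_factors=["grp"], residual="weighted", weight_col="w"),
            df,
        )
        blues = estimate_blues(fit, "grp")
        assert blues["blue"][0] == pytest.approx(np.sum(w * y) / np.sum(w), abs=1e-10)
        assert blues["se"][0] == pytest.approx(
            np.sqrt(fit.varcomp["sigma2_e"] / np.sum(w)), abs=1e-10
        )

    def test_alpha_lattice_blues_equal_dense_gls_oracle(self):
        """BLUE vector equals the explicit V^{-1} GLS solution."""
        from gaintrend.simdata import SimConfig, simulate_dataset

        cfg = SimConfig(n_years=1, crosses_per_year=6, progeny_per_cross=4, n_founders=20,
                        design_mix=(1.0, 0.0, 0.0), seed=42, true_trend=0.0,
                        selection_fraction=1.0)
        ds = simulate_dataset(cfg)
        trial = ds.phenotypes.query("trial == trial.iloc[0]").copy()
        spec = ModelSpec(
            response="yield_kg_ha",
            fixed_factors=["genotype"],
            random_terms=[RandomTerm("rep"), RandomTerm("rb")],
        )
        trial["rb"] = trial["rep"].astype(str) + ":" + trial["block"].astype(str)
        fit = reml_fit(spec, trial)
        blues = estimate_blues(fit, "genotype").set_index("level")

        # dense GLS oracle at the converged variance components
        genos = sorted(trial["genotype"].unique())
        X = pd.get_dummies(trial["genotype"]).astype(float)[genos].to_numpy()
        Zr = pd.get_dummies(trial["rep"]).astype(float).to_numpy()
        Zb = pd.get_dummies(trial["rb"]).astype(float).to_numpy()
        s2r, s2b = fit._theta[0], fit._theta[1]
        s2e = fit._theta[2]
        V = s2r * Zr @ Zr.T + s2b * Zb @ Zb.T + s2e * np.eye(len(trial))
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ trial["yield_kg_ha"].to_numpy())
        cov = np.linalg.inv(X.T @ Vi @ X)
        np.testing.assert_allclose(blues.loc[genos, "blue"].to_numpy(), beta, rtol=1e-8)
        np.testing.assert_allclose(
            blues.loc[genos, "se"].to_numpy(), np.sqrt(np.diag(cov)), rtol=1e-8
        )


class TestBlups:
    def test_single_obs_shrinkage_closed_form(self):
        rng = np.random.default_rng(11)
        names = [f"g{i:02d}" for i in range(40)]
        y = rng.normal(0, 2, 40) + rng.normal(0, 1, 40)
        df = pd.DataFrame({"y": y, "g": names})
        fit = reml_fit(ModelSpec(response="y", random_terms=[RandomTerm("g")]), df)
        k = fit._theta[0] / (fit._theta[0] + fit._theta[1])
        expected = k * (y - fit.beta[0])
        got = predict_blups(fit, "g")["blup"][names].to_numpy()
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_no_information_genotype_pev_tends_to_prior(self):
        """A genotype connected only through A has PEV -> sigma2_g * A_ii."""
        ped = load_and_sort_pedigree(
            [("S", None, None), ("D", None, None), ("A", "S", "D"), ("Z", None, None)]
        )
        A = build_a_matrix(ped)
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"y": 1.0 + rng.normal(0, 0.5, 8), "g": "A"})
        fit = reml_fit(
            ModelSpec(
                response="y",
                random_terms=[RandomTerm("g", covariance=A.values, cov_ids=A.ids,
                                         cov_inv=build_a_inverse(ped))],
            ),
            df,
        )
        s2g = fit._theta[0]
        # Z is unrelated to everything: no information at all
        assert fit.pev["g"]["Z"] == pytest.approx(s2g, rel=1e-8)

    def test_pedigree_blups_match_dense_mme_oracle(self):
        """BLUPs on a random 50-genotype pedigree equal the dense MME solution
        assembled by explicit blocks at the converged components."""
        rng = np.random.default_rng(77)
        trios = random_pedigree_trios(rng, 50)
        ped = load_and_sort_pedigree(trios)
        A = build_a_matrix(ped)
        obs_ids = list(rng.choice(ped.ids, size=30, replace=False))
        tbv = rng.multivariate_normal(np.zeros(len(A.ids)), 4.0 * A.values)
        tbv = pd.Series(tbv, index=A.ids)
        df = pd.DataFrame(
            {"y": 5.0 + tbv[obs_ids].to_numpy() + rng.normal(0, 1, 30), "g": obs_ids, "mu": "m"}
        )
        fit = reml_fit(
            ModelSpec(
                response="y",
                fixed_factors=["mu"],
                random_terms=[RandomTerm("g", covariance=A.values, cov_ids=A.ids,
                                         cov_inv=build_a_inverse(ped))],
            ),
            df,
        )
        s2g, s2e = fit._theta
        n = len(df)
        q = len(A.ids)
        Z = np.zeros((n, q))
        gidx = {g: j for j, g in enumerate(A.ids)}
        for i, g in enumerate(df["g"]):
            Z[i, gidx[g]] = 1.0
        X = np.ones((n, 1))
        Ainv = np.linalg.inv(A.values)
        C = np.block(
            [
                [X.T @ X / s2e, X.T @ Z / s2e],
                [Z.T @ X / s2e, Z.T @ Z / s2e + Ainv / s2g],
            ]
        )
        rhs = np.concatenate([X.T @ df["y"] / s2e, Z.T @ df["y"] / s2e])
        sol = np.linalg.solve(C, rhs)
        np.testing.assert_allclose(fit.beta, sol[:1], rtol=1e-6)
        np.testing.assert_allclose(
            fit.u["g"][list(A.ids)].to_numpy(), sol[1:], atol=1e-6
        )
        # normal-equation residual
        resid = C @ sol - rhs
        assert np.max(np.abs(resid)) / max(np.max(np.abs(rhs)), 1) < 1e-8

    def test_shrinkage_monotone_in_variance_ratio(self):
        """BLUPs approach group-mean BLUEs as sigma2_g -> inf and vanish as
        sigma2_g -> 0; shrinkage is monotone across variance ratios."""
        df = oneway_dataset(3)
        spec = ModelSpec(response="y", random_terms=[RandomTerm("g")])
        centered_means = df.groupby("g")["y"].mean() - df["y"].mean()
        norms = []
        for s2g in (1e-4, 1.0, 1e6):
            fit = reml_fit(spec, df, fixed_theta=[s2g, 1.0])
            u = predict_blups(fit, "g")["blup"]
            k = 5 * s2g / (5 * s2g + 1.0)
            np.testing.assert_allclose(
                u[centered_means.index], k * centered_means, atol=1e-6
            )
            norms.append(float(np.linalg.norm(u)))
        assert norms[0] < norms[1] < norms[2]
        assert norms[0] == pytest.approx(0.0, abs=1e-2)

    def test_unknown_term_fatal(self):
        df = oneway_dataset(0)
        fit = reml_fit(ModelSpec(response="y", random_terms=[RandomTerm("g")]), df)
        with pytest.raises(ModelError):
            predict_blups(fit, "nope")
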