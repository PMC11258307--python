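"""Tests of standardization, cluster-robust OLS/2SLS (against brute-force
sandwich oracles), first-stage diagnostics, and the four model specs."""

import numpy as np
import pandas as pd
import pytest

from triomr import (ModelSpec, fit_2sls_cluster, fit_ols_cluster,
                    first_stage_diagnostics, run_spec, standardize_outcome)


def sandwich_oracle(X, u, clusters, n, k):
    """Brute-force clustered sandwich with the G/(G-1)*(N-1)/(N-k) factor."""
    groups = pd.factorize(clusters)[0]
    g = groups.max() + 1
    A_inv = np.linalg.inv(X.T @ X)
    meat = np.zeros((X.shape[1], X.shape[1]))
    for c in range(g):
        s = (X[groups == c] * u[groups == c, None]).sum(axis=0)
        meat += np.outer(s, s)
    factor = (g / (g - 1)) * ((n - 1) / (n - k))
    return factor * A_inv @ meat @ A_inv


class TestStandardize:
    def test_two_point_arithmetic(self):
        out = standardize_outcome(np.array([0.0, 2.0]))
        np.testing.assert_allclose(out, [-0.7071067811865475, 0.7071067811865475])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        x = standardize_outcome(rng.normal(size=100))
        np.testing.assert_allclose(standardize_outcome(x), x, atol=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            standardize_outcome(np.ones(10))

    def test_supplied_moments_used(self):
        out = standardize_outcome(np.array([1.0, 3.0]), mean=1.0, sd=2.0)
        np.testing.assert_allclose(out, [0.0, 1.0])


class TestOlsCluster:
    def test_perfect_fit_zero_se(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        X = pd.DataFrame({"const": 1.0, "x": x})
        y = 2.0 + 3.0 * x
        fit = fit_ols_cluster(y, X, np.repeat(np.arange(20), 2))
        np.testing.assert_allclose(fit.params["se"], 0.0, atol=1e-8)
        np.testing.assert_allclose(fit.params["estimate"], [2.0, 3.0], atol=1e-10)

    def test_singleton_clusters_equal_hc1(self):
        rng = np.random.default_rng(2)
        n = 60
        X = pd.DataFrame({"const": 1.0, "x": rng.normal(size=n),
                          "z": rng.normal(size=n)})
        y = 1.0 + 0.5 * X["x"] + rng.normal(size=n)
        fit = fit_ols_cluster(y, X, np.arange(n))
        # HC1 oracle: (n/(n-k)) * A^-1 (sum x_i x_i' u_i^2) A^-1
        A = X.to_numpy()
        beta = np.linalg.lstsq(A, y, rcond=None)[0]
        u = y - A @ beta
        k = A.shape[1]
        A_inv = np.linalg.inv(A.T @ A)
        meat = (A * u.to_numpy()[:, None]).T @ (A * u.to_numpy()[:, None])
        V = (n / (n - k)) * A_inv @ meat @ A_inv
        np.testing.assert_allclose(fit.params["se"], np.sqrt(np.diag(V)), rtol=1e-10)

    def test_brute_force_sandwich_on_30_rows(self):
        rng = np.random.default_rng(3)
        n = 30
        X = pd.DataFrame({"const": 1.0, "x": rng.normal(size=n),
                          "w": rng.normal(size=n)})
        y = 0.3 * X["x"] + rng.normal(size=n)
        clusters = rng.integers(0, 10, size=n)
        fit = fit_ols_cluster(y.to_numpy(), X, clusters)
        A = X.to_numpy()
        beta = np.linalg.lstsq(A, y.to_numpy(), rcond=None)[0]
        u = y.to_numpy() - A @ beta
        V = sandwich_oracle(A, u, clusters, n, A.shape[1])
        np.testing.assert_allclose(fit.params["se"], np.sqrt(np.diag(V)), rtol=1e-10)

    def test_planted_slope_recovery_paired_clusters(self):
        rng = np.random.default_rng(4)
        n = 10_000
        cluster = np.repeat(np.arange(n // 2), 2)
        shared = rng.normal(size=n // 2)[cluster]
        x = rng.normal(size=n)
        y = 0.5 * x + shared + rng.normal(size=n)
        X = pd.DataFrame({"const": 1.0, "x": x})
        fit = fit_ols_cluster(y, X, cluster)
        rec = fit.term("x")
        assert abs(rec["estimate"] - 0.5) < 3 * rec["se"]
        assert fit.n_clusters == n // 2

    def test_collinear_column_dropped_with_warning(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        X = pd.DataFrame({"const": 1.0, "x": x, "x2": 2 * x})
        with pytest.warns(UserWarning, match="collinear"):
            fit = fit_ols_cluster(x + rng.normal(size=30), X, np.arange(30))
        assert fit.dropped_columns == ["x2"]

    def test_single_cluster_rejected(self):
        X = pd.DataFrame({"const": np.ones(10), "x": np.arange(10.0)})
        with pytest.raises(ValueError):
            fit_ols_cluster(np.arange(10.0), X, np.zeros(10))


class Test2sls:
    def test_instruments_equal_regressors_reduces_to_ols(self):
        rng = np.random.default_rng(6)
        n = 50
        x = rng.normal(size=n)
        y = 0.7 * x + rng.normal(size=n)
        exog = pd.DataFrame({"const": np.ones(n)})
        endog = pd.DataFrame({"x": x})
        clusters = rng.integers(0, 10, size=n)
        iv = fit_2sls_cluster(y, endog, endog.rename(columns={"x": "z"}), exog,
                              clusters, diagnostics=False)
        ols = fit_ols_cluster(y, pd.concat([exog, endog], axis=1), clusters)
        np.testing.assert_allclose(iv.term("x")["estimate"],
                                   ols.term("x")["estimate"], atol=1e-10)
        np.testing.assert_allclose(iv.term("x")["se"], ols.term("x")["se"],
                                   atol=1e-10)

    def test_hand_computed_wald_ratio(self):
        z = pd.DataFrame({"z": [0.0, 0.0, 1.0, 1.0]})
        x = pd.DataFrame({"x": [0.0, 1.0, 1.0, 2.0]})
        y = np.array([0.0, 0.0, 1.0, 1.0])
        exog = pd.DataFrame({"const": np.ones(4)})
        fit = fit_2sls_cluster(y, x, z, exog, np.arange(4), diagnostics=False)
        assert fit.term("x")["estimate"] == pytest.approx(1.0, abs=1e-10)

    def test_structural_residual_sandwich_oracle(self):
        rng = np.random.default_rng(7)
        n = 30
        z = rng.normal(size=n)
        x = 0.8 * z + rng.normal(size=n) * 0.5
        y = 0.4 * x + rng.normal(size=n)
        clusters = rng.integers(0, 8, size=n)
        exog = pd.DataFrame({"const": np.ones(n)})
        fit = fit_2sls_cluster(y, pd.DataFrame({"x": x}), pd.DataFrame({"z": z}),
                               exog, clusters, diagnostics=False)
        # oracle: explicit 2SLS with structural residuals
        Z = np.column_stack([np.ones(n), z])
        X = np.column_stack([np.ones(n), x])
        P = Z @ np.linalg.inv(Z.T @ Z) @ Z.T
        Xh = P @ X
        beta = np.linalg.solve(Xh.T @ Xh, Xh.T @ y)
        u = y - X @ beta  # structural, not second-stage, residuals
        groups = pd.factorize(clusters)[0]
        g = groups.max() + 1
        A_inv = np.linalg.inv(Xh.T @ Xh)
        meat = np.zeros((2, 2))
        for c in range(g):
            s = (Xh[groups == c] * u[groups == c, None]).sum(axis=0)
            meat += np.outer(s, s)
        V = (g / (g - 1)) * ((n - 1) / (n - 2)) * A_inv @ meat @ A_inv
        np.testing.assert_allclose(fit.params["estimate"], beta, atol=1e-10)
        np.testing.assert_allclose(fit.params["se"], np.sqrt(np.diag(V)), rtol=1e-10)

    def test_under_identification_rejected(self):
        n = 20
        rng = np.random.default_rng(8)
        endog = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        instr = pd.DataFrame({"z": rng.normal(size=n)})
        exog = pd.DataFrame({"const": np.ones(n)})
        with pytest.raises(ValueError, match="nder-identified"):
            fit_2sls_cluster(rng.normal(size=n), endog, instr, exog,
                             np.arange(n), diagnostics=False)


class TestFirstStage:
    def test_f_formula_matches_independent_recomputation(self):
        rng = np.random.default_rng(9)
        n = 12
        z = rng.normal(size=n)
        x = 0.9 * z + rng.normal(size=n) * 0.8
        exog = pd.DataFrame({"const": np.ones(n), "c": rng.normal(size=n)})
        diag = first_stage_diagnostics(pd.DataFrame({"x": x}),
                                       pd.DataFrame({"z": z}), exog, np.arange(n))

        def r2(yv, Xv):
            b = np.linalg.lstsq(Xv, yv, rcond=None)[0]
            res = yv - Xv @ b
            return 1 - res @ res / ((yv - yv.mean()) @ (yv - yv.mean()))

        Zfull = np.column_stack([exog.to_numpy(), z])
        r2f, r2r = r2(x, Zfull), r2(x, exog.to_numpy())
        k = Zfull.shape[1]
        expect = ((r2f - r2r) / 1) / ((1 - r2f) / (n - k))
        assert diag.f_stat["x"] == pytest.approx(expect, rel=1e-10)
        assert diag.partial_r2["x"] == pytest.approx(r2f - r2r, rel=1e-10)

    def test_toy_f_value_nine(self):
        # engineered so R2_full = 0.5, R2_reduced = 0, n=12, k=3, q=1:
        # F = (0.5/1)/((1-0.5)/9) = 9
        n = 12
        c = np.resize([1.0, -1.0], n)          # exog covariate, orthogonal to z
        z = np.resize([1.0, 1.0, -1.0, -1.0], n)
        e = np.resize([1.0, -1.0, -1.0, 1.0, 1.0, 1.0, -1.0, -1.0], n)
        e = e - e.mean()
        # make e orthogonal to both z and c, unit-matched variance with z
        e = e - z * (e @ z) / (z @ z) - c * (e @ c) / (c @ c)
        e = e * np.sqrt((z @ z) / (e @ e))
        x = z + e                               # var split 50/50
        exog = pd.DataFrame({"const": np.ones(n), "c": c})
        diag = first_stage_diagnostics(pd.DataFrame({"x": x}),
                                       pd.DataFrame({"z": z}), exog, np.arange(n))
        assert diag.f_stat["x"] == pytest.approx(9.0, rel=1e-8)

    def test_null_instrument_rarely_exceeds_ten(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            n = 500
            z = rng.normal(size=n)
            x = rng.normal(size=n)  # instrument irrelevant
            exog = pd.DataFrame({"const": np.ones(n)})
            diag = first_stage_diagnostics(pd.DataFrame({"x": x}),
                                           pd.DataFrame({"z": z}), exog,
                                           np.arange(n))
            hits += diag.f_stat["x"] > 10
        assert hits <= 3  # ~5% would be 2.5; allow binomial slack


class TestRunSpec:
    def test_wfmr_recovers_direct_effect_and_null_education(self, scored_cohort):
        # planted eta = -0.1, beta_m = beta_f = 0 in the session cohort
        pheno = scored_cohort.phenotypes
        fit = run_spec(pheno, ModelSpec(spec="wfmr", outcome="smfq"))
        sd_out = pheno["smfq"].std(ddof=1)
        child = fit.term("pgi_child")
        assert abs(child["estimate"] * sd_out - (-0.1)) < 3.5 * child["se"] * sd_out
        for term in ("edu_mother_years", "edu_father_years"):
            rec = fit.term(term)
            assert abs(rec["estimate"] / rec["se"]) < 3.5

    def test_confounding_contrast_between_specs(self):
        import triomr
        sig_ols, null_wfmr = 0, 0
        n_seeds = 5
        for seed in range(n_seeds):
            cfg = triomr.SimConfig(n_families=10_000, n_snps=60, seed=700 + seed,
                                   conf_edu=0.6, conf_outcome=0.6, n_pcs=0,
                                   related_fraction=0.0)
            cohort = triomr.simulate_trio_cohort(cfg)
            pheno = cohort.phenotypes
            w = cohort.panel["true_weight"].to_numpy()
            for role in ("mother", "father", "child"):
                raw = cohort.dosages[role].astype(float) @ w
                pheno[f"pgi_{role}"] = (raw - raw.mean()) / raw.std(ddof=1)
            ols = run_spec(pheno, ModelSpec(spec="ols_minimal", outcome="smfq"))
            wf = run_spec(pheno, ModelSpec(spec="wfmr", outcome="smfq"))
            z_ols = abs(ols.term("edu_mother_years")["estimate"]
                        / ols.term("edu_mother_years")["se"])
            z_wf = abs(wf.term("edu_mother_years")["estimate"]
                       / wf.term("edu_mother_years")["se"])
            sig_ols += z_ols > 2
            null_wfmr += z_wf < 3.5
        assert sig_ols >= n_seeds - 1
        assert null_wfmr >= n_seeds - 1

    def test_nurture_truth_mr_equals_wfmr(self):
        import triomr
        cfg = triomr.SimConfig(n_families=10_000, n_snps=60, seed=811,
                               beta_mother=-0.02, eta=0.0, n_pcs=0,
                               related_fraction=0.0)
        cohort = triomr.simulate_trio_cohort(cfg)
        pheno = cohort.phenotypes
        w = cohort.panel["true_weight"].to_numpy()
        for role in ("mother", "father", "child"):
            raw = cohort.dosages[role].astype(float) @ w
            pheno[f"pgi_{role}"] = (raw - raw.mean()) / raw.std(ddof=1)
        mr = run_spec(pheno, ModelSpec(spec="mr", outcome="smfq"))
        wf = run_spec(pheno, ModelSpec(spec="wfmr", outcome="smfq"))
        a, b = mr.term("edu_mother_years"), wf.term("edu_mother_years")
        joint_se = np.hypot(a["se"], b["se"])
        assert abs(a["estimate"] - b["estimate"]) < 3 * joint_se

    def test_per_parent_mode_and_spec_validation(self, scored_cohort):
        fit = run_spec(scored_cohort.phenotypes,
                       ModelSpec(spec="wfmr", outcome="smfq", per_parent="mother"))
        assert "edu_mother_years" in fit.params.index
        assert "pgi_father" in fit.params.index  # other parent's PGI as covariate
        with pytest.raises(ValueError):
            ModelSpec(spec="ols_minimal", outcome="smfq", per_parent="mother")
        with pytest.raises(ValueError):
            ModelSpec(spec="anova", outcome="smfq")

    def test_sqrt_and_sex_options(self, scored_cohort):
        fit = run_spec(scored_cohort.phenotypes,
                       ModelSpec(spec="ols_minimal", outcome="smfq",
                                 sqrt_transform=True, sex=1))
        assert fit.n == int((scored_cohort.phenotypes["child_sex"] == 1).sum())
        assert "child_sex" not in fit.params.index

    def test_pooled_fit_over_imputed_stack(self, scored_cohort):
        import triomr
        pheno = scored_cohort.phenotypes.copy()
        rng = np.random.default_rng(12)
        pheno.loc[rng.random(len(pheno)) < 0.3, "smfq"] = np.nan
        cfg = triomr.ImputationConfig(
            m=3, knn=5, n_cycles=2, seed=6,
            variables={"smfq": "continuous"},
            predictors=["edu_mother_years", "edu_father_years", "pgi_child",
                        "pgi_mother", "pgi_father", "child_sex"])
        cd = triomr.chained_impute(pheno, cfg)
        fit = run_spec(cd, ModelSpec(spec="wfmr", outcome="smfq"))
        assert np.isfinite(fit.term("pgi_child")["se"])
        assert fit.n == len(pheno)
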