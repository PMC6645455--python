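"""GLS estimation, lambda profiling, and the single-model PGLS fit."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

import pglsverse as pv
from pglsverse.pgls import LambdaProfiler, build_design

from conftest import star_vcv


def explicit_gls(y, X, V):
    """Independent oracle: the textbook estimator by dense inversion."""
    Vi = np.linalg.inv(V)
    b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    resid = y - X @ b
    rss_w = float(resid @ Vi @ resid)
    cov = rss_w / (len(y) - X.shape[1]) * np.linalg.inv(X.T @ Vi @ X)
    return b, np.sqrt(np.diag(cov))


def random_instance(rng, n, p):
    A = rng.standard_normal((n, n))
    V = A @ A.T + n * np.eye(n)
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
    y = rng.standard_normal(n)
    return y, X, V


class TestFitGLS:
    def test_identity_v_reduces_to_ols(self, rng):
        y, X, _ = random_instance(rng, 30, 3)
        res = pv.fit_gls(y, X, np.eye(30))
        ols = sm.OLS(y, X).fit()
        assert np.allclose(res.beta, ols.params, atol=1e-10)
        assert np.allclose(res.se, ols.bse, atol=1e-10)

    def test_intercept_only_matches_explicit_formula(self):
        V = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
        y = np.array([1.0, 2.0, 3.0])
        X = np.ones((3, 1))
        Vi = np.linalg.inv(V)
        expected = (X.T @ Vi @ y) / (X.T @ Vi @ X)
        res = pv.fit_gls(y, X, V)
        assert res.beta[0] == pytest.approx(expected.item(), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_whitening_equals_dense_inverse_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y, X, V = random_instance(rng, 12, 3)
        res = pv.fit_gls(y, X, V)
        b, se = explicit_gls(y, X, V)
        assert np.allclose(res.beta, b, atol=1e-9)
        assert np.allclose(res.se, se, atol=1e-9)

    def test_duplicate_column_raises_naming_alias(self, rng):
        y, X, V = random_instance(rng, 20, 3)
        X2 = np.column_stack([X, X[:, 1]])
        with pytest.raises(pv.PGLSError, match="rank-deficient"):
            pv.fit_gls(y, X2, V, term_names=["int", "a", "b", "a_copy"])

    def test_singular_v_names_taxa_pair(self, rng):
        V = np.ones((4, 4))  # four identical tips
        y = rng.standard_normal(4)
        X = np.ones((4, 1))
        vm = pv.VCVMatrix(["w", "x", "y", "z"], V)
        with pytest.raises(pv.PGLSError, match="singular"):
            pv.fit_gls(y, X, vm)

    def test_loglik_matches_mvnormal_density(self, rng):
        y, X, V = random_instance(rng, 15, 2)
        res = pv.fit_gls(y, X, V)
        ll = stats.multivariate_normal.logpdf(y, mean=X @ res.beta, cov=res.sigma2 * V)
        assert res.loglik == pytest.approx(ll, abs=1e-8)


class TestLambdaProfile:
    def test_profile_matches_definitional_fit_gls(self):
        tree = pv.simulate_tree(30, seed=5)
        V = tree.vcv()
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(30), rng.standard_normal(30)])
        y = rng.standard_normal(30)
        prof = LambdaProfiler(y, X, V)
        for lam in (0.0, 0.5, 1.0):
            assert prof.loglik(lam) == pytest.approx(
                pv.profile_loglik(y, X, V, lam), abs=1e-8
            )

    @pytest.mark.parametrize("true_lam,where", [(0.0, "low"), (1.0, "high")])
    def test_profile_maximized_near_truth(self, true_lam, where):
        tree = pv.simulate_tree(100, seed=2)
        preds = pv.simulate_predictors(tree, np.eye(1), lambda_pred=0.5, seed=3)
        y = pv.simulate_response(preds, [0.0, 0.5], tree, lambda_resid=true_lam,
                                 sigma2=1.0, seed=4)
        df = preds.data.copy()
        df["y"] = y
        spec = pv.ModelSpec("y", focal=("pred1",))
        yv, X, taxa = build_design(df, spec)
        V = tree.vcv().reorder(taxa)
        lam_hat, fixed = pv.estimate_lambda(yv, X, V)
        assert not fixed
        assert (lam_hat < 0.35) if where == "low" else (lam_hat > 0.65)

    def test_optimum_beats_every_grid_point(self):
        tree = pv.simulate_tree(50, seed=8)
        rng = np.random.default_rng(8)
        X = np.column_stack([np.ones(50), rng.standard_normal(50)])
        V = tree.vcv()
        y = pv.simulate_response(
            pd.DataFrame(X[:, 1:], index=V.taxa, columns=["x"]),
            [0.0, 0.3], tree, lambda_resid=0.6, sigma2=0.5, seed=9,
        ).to_numpy()
        lam_hat, fixed = pv.estimate_lambda(y, X, V)
        assert not fixed
        best = pv.profile_loglik(y, X, V, lam_hat)
        grid = [pv.profile_loglik(y, X, V, l) for l in np.linspace(0, 1, 101)]
        assert best >= max(grid) - 1e-7

    def test_star_tree_falls_back_flagged(self, rng):
        V = star_vcv(20)
        X = np.column_stack([np.ones(20), rng.standard_normal(20)])
        y = rng.standard_normal(20)
        lam, fixed = pv.estimate_lambda(y, X, V)
        assert (lam, fixed) == (1.0, True)

    def test_fixed_policy(self, rng):
        V = star_vcv(10)
        X = np.ones((10, 1))
        y = rng.standard_normal(10)
        assert pv.estimate_lambda(y, X, V, policy="fixed:1") == (1.0, True)
        assert pv.estimate_lambda(y, X, V, policy="fixed:0.3") == (0.3, True)

    def test_lambda_recovery_simulation(self):
        """lambda-hat within +/-0.15 of the generating 0.7 in >=90% of seeds."""
        tree = pv.simulate_tree(200, seed=1)
        V = tree.vcv()
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            preds = pv.simulate_predictors(tree, np.eye(1), lambda_pred=0.3, seed=100 + seed)
            y = pv.simulate_response(preds, [0.0, 0.4], tree, lambda_resid=0.7,
                                     sigma2=1.0, seed=200 + seed)
            X = np.column_stack([np.ones(200), preds.data.loc[V.taxa].to_numpy()])
            lam, fixed = pv.estimate_lambda(y.loc[V.taxa].to_numpy(), X, V)
            hits += (not fixed) and abs(lam - 0.7) <= 0.15
        assert hits >= 0.9 * n_seeds


class TestFitPGLS:
    def test_zero_focal_reduces_to_covariate_model(self, paper_like):
        tree, table = paper_like
        spec = pv.ModelSpec("total_brain", focal=(), mandatory=("female_weight",))
        fit = pv.fit_pgls(table.data, spec, tree)
        assert fit.terms == ("(Intercept)", "female_weight")
        assert fit.n == 40

    def test_row_order_invariance(self, paper_like):
        tree, table = paper_like
        spec = pv.ModelSpec("total_brain", focal=("life_span",),
                            mandatory=("female_weight",))
        fit1 = pv.fit_pgls(table.data, spec, tree)
        shuffled = table.data.sample(frac=1.0, random_state=3)
        fit2 = pv.fit_pgls(shuffled, spec, tree)
        for attr in ("beta", "se", "t_values", "p_values"):
            assert np.allclose(getattr(fit1, attr), getattr(fit2, attr), atol=1e-10)
        assert fit1.aic == pytest.approx(fit2.aic, abs=1e-10)

    def test_t_and_p_consistency(self, paper_like):
        tree, table = paper_like
        spec = pv.ModelSpec("neocortex", focal=("fruit",), mandatory=("female_weight",))
        fit = pv.fit_pgls(table.data, spec, tree)
        assert np.allclose(fit.t_values, fit.beta / fit.se)
        expect_p = 2 * stats.t.sf(np.abs(fit.t_values), fit.df_resid)
        assert np.allclose(fit.p_values, expect_p)

    def test_insufficient_species_error(self, three_tip_tree):
        df = pd.DataFrame(
            {"y": [1.0, 2.0, 3.0], "a": [0.1, 0.2, 0.3], "b": [1.0, 0.0, 1.0]},
            index=["A", "B", "C"],
        )
        with pytest.raises(pv.PGLSError, match="insufficient species"):
            pv.fit_pgls(df, pv.ModelSpec("y", focal=("a", "b")), three_tip_tree)

    def test_scaling_response_scales_b_se_leaves_t_p_r2(self, paper_like):
        tree, table = paper_like
        spec = pv.ModelSpec("total_brain", focal=("life_span",),
                            mandatory=("female_weight",))
        fit1 = pv.fit_pgls(table.data, spec, tree)
        scaled = table.data.copy()
        scaled["total_brain"] = 3.0 * scaled["total_brain"]
        fit2 = pv.fit_pgls(scaled, spec, tree)
        assert np.allclose(fit2.beta, 3.0 * fit1.beta, rtol=1e-6)
        assert np.allclose(fit2.se, 3.0 * fit1.se, rtol=1e-6)
        assert np.allclose(fit2.t_values, fit1.t_values, rtol=1e-6)
        assert np.allclose(fit2.p_values, fit1.p_values, atol=1e-8)
        assert fit2.r2 == pytest.approx(fit1.r2, abs=1e-8)
        assert fit2.lam == pytest.approx(fit1.lam, abs=1e-4)

    def test_noiseless_data_recovers_beta_exactly(self):
        tree = pv.simulate_tree(25, seed=6)
        preds = pv.simulate_predictors(tree, np.eye(2), seed=7, names=["a", "b"])
        y = pv.simulate_response(preds, [1.0, 0.5, -0.25], tree, sigma2=0.0, seed=8)
        df = preds.data.copy()
        df["y"] = y
        fit = pv.fit_pgls(df, pv.ModelSpec("y", focal=("a", "b")), tree,
                          policy="fixed:1")
        assert np.allclose(fit.beta, [1.0, 0.5, -0.25], atol=1e-8)


class TestDegenerateLimits:
    """lambda = 0 and star phylogenies must reproduce OLS exactly."""

    def _fit_and_ols(self, policy, tree, df, spec):
        fit = pv.fit_pgls(df, spec, tree, policy=policy)
        sub = df.loc[list(fit.taxa)]
        X = np.column_stack([np.ones(fit.n)] +
                            [sub[c].to_numpy() for c in spec.predictors])
        ols = sm.OLS(sub[spec.outcome].to_numpy(), X).fit()
        return fit, ols

    def test_lambda_zero_on_ultrametric_tree_is_ols(self, paper_like):
        tree, table = paper_like
        spec = pv.ModelSpec("total_brain", focal=("life_span", "fruit"),
                            mandatory=("female_weight",))
        fit, ols = self._fit_and_ols("fixed:0", tree, table.data, spec)
        assert np.allclose(fit.beta, ols.params, atol=1e-8)
        assert np.allclose(fit.se, ols.bse, atol=1e-8)
        assert np.allclose(fit.p_values, ols.pvalues, atol=1e-8)

    @pytest.mark.parametrize("lam", ["fixed:0", "fixed:0.5", "fixed:1"])
    def test_star_tree_is_ols_for_every_lambda(self, lam, rng):
        tree = pv.read_newick("(" + ",".join(f"t{i}:1" for i in range(20)) + ");")
        df = pd.DataFrame(
            {"y": rng.standard_normal(20), "x": rng.standard_normal(20)},
            index=[f"t{i}" for i in range(20)],
        )
        fit, ols = self._fit_and_ols(lam, tree, df, pv.ModelSpec("y", focal=("x",)))
        assert np.allclose(fit.beta, ols.params, atol=1e-8)
        assert np.allclose(fit.se, ols.bse, atol=1e-8)


class TestAIC:
    def test_formula(self):
        assert pv.aic(-10.0, n_terms=3, lambda_estimated=True) == pytest.approx(30.0)
        assert pv.aic(-10.0, n_terms=3, lambda_estimated=False) == pytest.approx(28.0)

    def test_equal_loglik_nested_models_differ_by_two(self):
        small = pv.aic(-5.0, n_terms=2, lambda_estimated=False)
        large = pv.aic(-5.0, n_terms=3, lambda_estimated=False)
        assert large - small == pytest.approx(2.0)

    def test_fit_aic_consistent_with_formula(self, paper_like):
        tree, table = paper_like
        spec = pv.ModelSpec("total_brain", focal=("fruit",), mandatory=("female_weight",))
        fit = pv.fit_pgls(table.data, spec, tree)
        k = len(fit.terms) + 1 + (0 if fit.lambda_fixed else 1)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * k, abs=1e-10)


class TestRSquared:
    def test_perfect_fit(self, rng):
        y = rng.standard_normal(10)
        assert pv.r_squared(y, y) == pytest.approx(1.0)

    def test_constant_fitted_errors(self):
        with pytest.raises(pv.PGLSError, match="zero variance"):
            pv.r_squared(np.ones(5), np.arange(5.0))

    def test_matches_direct_correlation(self, rng):
        f = rng.standard_normal(50)
        y = f + rng.standard_normal(50)
        assert pv.r_squared(f, y) == pytest.approx(np.corrcoef(f, y)[0, 1] ** 2)


class TestPredict:
    def _simple_fit(self, rng, n=30):
        tree = pv.read_newick("(" + ",".join(f"t{i}:1" for i in range(n)) + ");")
        x = rng.standard_normal(n)
        y = 1.0 + 2.0 * x + rng.standard_normal(n)
        df = pd.DataFrame({"y": y, "x": x}, index=[f"t{i}" for i in range(n)])
        return pv.fit_pgls(df, pv.ModelSpec("y", focal=("x",)), tree,
                           policy="fixed:1"), df

    def test_point_equals_fitted_for_modeled_species(self, rng):
        fit, df = self._simple_fit(rng)
        sp = fit.taxa[4]
        pred = pv.predict(fit, {"x": df.loc[sp, "x"]})
        assert pred.point == pytest.approx(fit.fitted[4], abs=1e-10)

    def test_wider_level_gives_wider_interval(self, rng):
        fit, _ = self._simple_fit(rng)
        p95 = pv.predict(fit, {"x": 0.5}, level=0.95)
        p50 = pv.predict(fit, {"x": 0.5}, level=0.5)
        assert p95.interval_low < p50.interval_low < p50.interval_high < p95.interval_high

    def test_matches_ols_closed_form_under_identity_v(self, rng):
        fit, df = self._simple_fit(rng)
        X = np.column_stack([np.ones(len(df)), df["x"]])
        ols = sm.OLS(df["y"].to_numpy(), X).fit()
        x0 = 0.7
        sf = ols.get_prediction([1.0, x0]).summary_frame(alpha=0.05)
        pred = pv.predict(fit, {"x": x0}, level=0.95)
        assert pred.point == pytest.approx(sf["mean"].iloc[0], abs=1e-8)
        assert pred.interval_low == pytest.approx(sf["obs_ci_lower"].iloc[0], abs=1e-6)
        assert pred.interval_high == pytest.approx(sf["obs_ci_upper"].iloc[0], abs=1e-6)

    def test_missing_predictor_raises(self, rng):
        fit, _ = self._simple_fit(rng)
        with pytest.raises(pv.PGLSError, match="missing"):
            pv.predict(fit, {})

    def test_exponentiated_log_interval_is_asymmetric(self, rng):
        fit, _ = self._simple_fit(rng)
        pred = pv.predict(fit, {"x": 0.3})
        lo, mid, hi = np.exp([pred.interval_low, pred.point, pred.interval_high])
        assert hi - mid > mid - lo  # asymmetry after back-transform
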