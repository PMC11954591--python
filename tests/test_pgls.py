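import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from phylocna import (
    CovarianceMatrix,
    DesignSpec,
    bm_covariance,
    coefficient_test,
    fit_gls,
    fit_pgls,
    fit_poisson_pglm,
    generate_tree,
    lambda_transform,
    parse_newick,
)
from phylocna.pgls import LambdaProfiler, RankError
from phylocna.tree import sample_mvn_bm

from conftest import random_tree


def normal_equations_oracle(y, X, C, weights=None):
    """Explicit matrix-inversion GLS: the spec'd independent oracle."""
    if weights is not None:
        sw = 1.0 / np.sqrt(weights)
        C = C * np.outer(sw, sw)
    Ci = np.linalg.inv(C)
    XtCiX = X.T @ Ci @ X
    beta = np.linalg.inv(XtCiX) @ X.T @ Ci @ y
    resid = y - X @ beta
    n, p = X.shape
    sigma2 = (resid @ Ci @ resid) / (n - p)
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtCiX)))
    return beta, se, sigma2


def random_gls_instance(rng, n=None, p=None):
    n = n or int(rng.integers(5, 13))
    p = p or int(rng.integers(1, min(3, n - 2) + 1))
    tree = random_tree(n, rng)
    V = bm_covariance(tree)
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p))])
    y = rng.standard_normal(n) * 2.0
    return tree, V, X, y


class TestFitGls:
    def test_intercept_only_is_mean(self):
        C = CovarianceMatrix(("a", "b", "c"), np.eye(3))
        design = DesignSpec(
            response=pd.Series([1.0, 2.0, 3.0], index=list("abc")),
            predictors=pd.DataFrame(index=list("abc")),
        )
        fit = fit_gls(design, C)
        assert fit.beta["intercept"] == pytest.approx(2.0)

    def test_exact_fit_zero_residual(self):
        C = CovarianceMatrix(tuple("abcd"), np.eye(4))
        x = pd.Series([0.0, 1.0, 2.0, 3.0], index=list("abcd"))
        y = 1.5 + 2.0 * x
        fit = fit_gls(
            DesignSpec(response=y, predictors=pd.DataFrame({"x": x})), C
        )
        assert fit.beta["intercept"] == pytest.approx(1.5, abs=1e-10)
        assert fit.beta["x"] == pytest.approx(2.0, abs=1e-10)
        assert fit.sigma2_hat == pytest.approx(0.0, abs=1e-18)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(17)
        tree, V, X, y = random_gls_instance(rng, n=5, p=1)
        design = DesignSpec(
            response=pd.Series(y, index=V.labels),
            predictors=pd.DataFrame(X[:, 1:], index=V.labels, columns=["x1"]),
        )
        fit = fit_gls(design, V)
        beta, se, sigma2 = normal_equations_oracle(y, X, V.values)
        assert np.allclose(fit.beta.to_numpy(), beta, rtol=1e-8)
        assert np.allclose(fit.se.to_numpy(), se, rtol=1e-8)
        assert fit.sigma2_hat == pytest.approx(sigma2, rel=1e-8)

    def test_property_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(60):
            tree, V, X, y = random_gls_instance(rng)
            w = rng.uniform(0.5, 4.0, size=len(y))
            cols = {f"x{j}": X[:, j] for j in range(1, X.shape[1])}
            design = DesignSpec(
                response=pd.Series(y, index=V.labels),
                predictors=pd.DataFrame(cols, index=V.labels),
                weights=pd.Series(w, index=V.labels),
            )
            fit = fit_gls(design, V)
            beta, se, sigma2 = normal_equations_oracle(y, X, V.values, w)
            assert np.allclose(fit.beta.to_numpy(), beta, rtol=1e-8)
            assert np.allclose(fit.se.to_numpy(), se, rtol=1e-8)

    def test_singular_design_names_columns(self):
        C = CovarianceMatrix(tuple("abcd"), np.eye(4))
        x = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        design = DesignSpec(
            response=pd.Series([1.0, 2, 3, 4], index=list("abcd")),
            predictors=pd.DataFrame({"x": x, "x_copy": 2 * x}),
        )
        with pytest.raises(RankError, match="rank deficient"):
            fit_gls(design, C)

    def test_loglik_matches_mvn_density(self):
        # ML loglik should equal the multivariate normal density at
        # (beta_hat, sigma2_ml)
        rng = np.random.default_rng(3)
        tree, V, X, y = random_gls_instance(rng, n=8, p=1)
        design = DesignSpec(
            response=pd.Series(y, index=V.labels),
            predictors=pd.DataFrame({"x1": X[:, 1]}, index=V.labels),
        )
        fit = fit_gls(design, V)
        n = len(y)
        beta, _, _ = normal_equations_oracle(y, X, V.values)
        resid = y - X @ beta
        sigma2_ml = (resid @ np.linalg.solve(V.values, resid)) / n
        ll = stats.multivariate_normal.logpdf(
            y, mean=X @ beta, cov=sigma2_ml * V.values
        )
        assert fit.loglik == pytest.approx(ll, rel=1e-10)


class TestFitPgls:
    def test_grid_search_oracle(self):
        rng = np.random.default_rng(8)
        tree = generate_tree(60, 4)
        V = bm_covariance(tree)
        y = sample_mvn_bm(
            lambda_transform(V, 0.6).values, 1.0, 0.0, rng, 1
        )[0]
        x = rng.standard_normal(60)
        design = DesignSpec(
            response=pd.Series(y, index=tree.tips),
            predictors=pd.DataFrame({"x": x}, index=tree.tips),
        )
        fit = fit_pgls(design, tree)
        prof = LambdaProfiler(V)
        X = np.column_stack([np.ones(60), x])
        ystar, Xstar = prof.transform(y), prof.transform(X)
        grid = [
            prof.profile_loglik(ystar, Xstar, lam)
            for lam in np.linspace(0, 1, 101)
        ]
        assert max(grid) <= fit.loglik + 1e-6

    def test_boundary_optimality(self):
        rng = np.random.default_rng(21)
        tree = generate_tree(50, 5)
        y = rng.standard_normal(50)
        design = DesignSpec(
            response=pd.Series(y, index=tree.tips),
            predictors=pd.DataFrame(index=tree.tips),
        )
        fit = fit_pgls(design, tree)
        for lam in (0.0, 1.0):
            alt = fit_pgls(design, tree, lam=lam)
            assert fit.loglik >= alt.loglik - 1e-9

    def test_lambda_zero_equals_ols(self):
        rng = np.random.default_rng(2)
        tree = generate_tree(40, 6)
        y = rng.standard_normal(40)
        x = rng.standard_normal(40)
        design = DesignSpec(
            response=pd.Series(y, index=tree.tips),
            predictors=pd.DataFrame({"x": x}, index=tree.tips),
        )
        fit = fit_pgls(design, tree, lam=0.0)
        # tree is ultrametric with unit height, so lambda=0 covariance is
        # the identity scaled -> coefficients equal OLS
        X = np.column_stack([np.ones(40), x])
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(fit.beta.to_numpy(), ols, rtol=1e-8)

    def test_lambda_recovery_quick(self):
        # reduced version of the acceptance criterion
        tree = generate_tree(150, 12)
        V = bm_covariance(tree)
        lam_hats = {0.0: [], 1.0: []}
        rng = np.random.default_rng(55)
        for lam_true in lam_hats:
            Vl = lambda_transform(V, lam_true)
            for _ in range(10):
                y = sample_mvn_bm(Vl.values, 1.0, 0.0, rng, 1)[0]
                design = DesignSpec(
                    response=pd.Series(y, index=tree.tips),
                    predictors=pd.DataFrame(index=tree.tips),
                )
                lam_hats[lam_true].append(fit_pgls(design, tree).lambda_hat)
        assert np.median(lam_hats[0.0]) <= 0.2
        assert np.median(lam_hats[1.0]) >= 0.8

    def test_weights_scale_invariance(self):
        rng = np.random.default_rng(31)
        tree = generate_tree(30, 7)
        y = rng.standard_normal(30)
        x = rng.standard_normal(30)
        w = rng.uniform(1, 10, 30)
        kw = dict(
            response=pd.Series(y, index=tree.tips),
            predictors=pd.DataFrame({"x": x}, index=tree.tips),
        )
        fit1 = fit_pgls(
            DesignSpec(weights=pd.Series(w, index=tree.tips), **kw), tree
        )
        fit2 = fit_pgls(
            DesignSpec(weights=pd.Series(2 * w, index=tree.tips), **kw), tree
        )
        assert np.allclose(fit1.beta.to_numpy(), fit2.beta.to_numpy(),
                           rtol=1e-7)
        assert np.allclose(fit1.tstats.to_numpy(), fit2.tstats.to_numpy(),
                           rtol=1e-6)

    def test_insufficient_data(self):
        tree = parse_newick("(A:1,B:1);")
        design = DesignSpec(
            response=pd.Series([1.0, 2.0], index=["A", "B"]),
            predictors=pd.DataFrame({"x": [0.0, 1.0]}, index=["A", "B"]),
        )
        with pytest.raises(ValueError, match="insufficient"):
            fit_pgls(design, tree)


class TestCoefficientTest:
    def test_zero_beta(self):
        C = CovarianceMatrix(tuple("abcde"), np.eye(5))
        y = pd.Series([1.0, -1.0, 1.0, -1.0, 0.0], index=list("abcde"))
        x = pd.Series([1.0, 1.0, -1.0, -1.0, 0.0], index=list("abcde"))
        fit = fit_gls(DesignSpec(response=y, predictors=pd.DataFrame({"x": x})), C)
        t, p = coefficient_test(fit, "x")
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_t2_df30_numerical_integration_oracle(self):
        # independent oracle: integrate the t density rather than call the
        # same distribution-function code path
        df = 30

        def density(u):
            from math import gamma, pi, sqrt

            return (
                gamma((df + 1) / 2)
                / (sqrt(df * pi) * gamma(df / 2))
                * (1 + u**2 / df) ** (-(df + 1) / 2)
            )

        tail, _ = integrate.quad(density, 2.0, np.inf)
        expected = 2 * tail
        assert expected == pytest.approx(0.0546, abs=5e-4)
        assert 2 * stats.t.sf(2.0, df) == pytest.approx(expected, rel=1e-8)

    def test_sign_symmetry(self):
        rng = np.random.default_rng(44)
        C = CovarianceMatrix(tuple("abcdefgh"), np.eye(8))
        x = rng.standard_normal(8)
        y = rng.standard_normal(8)
        idx = list("abcdefgh")
        fit_pos = fit_gls(
            DesignSpec(
                response=pd.Series(y, index=idx),
                predictors=pd.DataFrame({"x": x}, index=idx),
            ),
            C,
        )
        fit_neg = fit_gls(
            DesignSpec(
                response=pd.Series(-y, index=idx),
                predictors=pd.DataFrame({"x": x}, index=idx),
            ),
            C,
        )
        assert coefficient_test(fit_pos, "x")[1] == pytest.approx(
            coefficient_test(fit_neg, "x")[1], rel=1e-12
        )

    def test_unknown_term(self):
        C = CovarianceMatrix(("a", "b", "c"), np.eye(3))
        fit = fit_gls(
            DesignSpec(
                response=pd.Series([1.0, 2, 3], index=list("abc")),
                predictors=pd.DataFrame(index=list("abc")),
            ),
            C,
        )
        with pytest.raises(KeyError, match="unknown term"):
            coefficient_test(fit, "nope")

    def test_null_pvalues_uniform(self):
        # p-values of a null slope should be U(0,1): KS over 2,000 fits
        rng = np.random.default_rng(1234)
        n = 15
        labels = [f"s{i}" for i in range(n)]
        C = CovarianceMatrix(tuple(labels), np.eye(n))
        pvals = []
        for _ in range(2000):
            y = rng.standard_normal(n)
            x = rng.standard_normal(n)
            fit = fit_gls(
                DesignSpec(
                    response=pd.Series(y, index=labels),
                    predictors=pd.DataFrame({"x": x}, index=labels),
                ),
                C,
            )
            pvals.append(coefficient_test(fit, "x")[1])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestPoissonPglm:
    def test_star_tree_matches_irls_oracle(self):
        n = 40
        text = "(" + ",".join(f"s{i}:1" for i in range(n)) + ");"
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tree = parse_newick(text)
        rng = np.random.default_rng(9)
        x = rng.standard_normal(n)
        mu = np.exp(0.5 + 0.4 * x)
        y = rng.poisson(mu)
        labels = [f"s{i}" for i in range(n)]
        counts = pd.Series(y, index=labels)
        fit = fit_poisson_pglm(
            counts, pd.DataFrame({"x": x}, index=labels), tree, lam=0.0
        )
        # independent IRLS oracle
        X = np.column_stack([np.ones(n), x])
        beta = np.zeros(2)
        beta[0] = np.log(y.mean())
        for _ in range(200):
            eta = X @ beta
            m = np.exp(eta)
            W = np.diag(m)
            z = eta + (y - m) / m
            beta_new = np.linalg.solve(X.T @ W @ X, X.T @ W @ z)
            if np.max(np.abs(beta_new - beta)) < 1e-14:
                beta = beta_new
                break
            beta = beta_new
        assert np.allclose(fit.beta.to_numpy(), beta, atol=1e-6)
        # model-based SEs equal GLM SEs on the star tree
        eta = X @ beta
        cov = np.linalg.inv(X.T @ np.diag(np.exp(eta)) @ X)
        assert np.allclose(fit.se.to_numpy(), np.sqrt(np.diag(cov)),
                           rtol=1e-5)

    def test_constant_counts(self):
        tree = generate_tree(50, 8)
        rng = np.random.default_rng(10)
        c = 5
        counts = pd.Series(c, index=tree.tips)
        x = pd.Series(rng.standard_normal(50), index=tree.tips)
        fit = fit_poisson_pglm(counts, pd.DataFrame({"x": x}), tree, lam=0.0)
        assert abs(fit.beta["x"]) <= 2 * fit.se["x"] + 1e-8
        assert fit.beta["intercept"] == pytest.approx(np.log(c), abs=0.05)

    def test_sign_recovery(self):
        tree = generate_tree(94, 13)
        rng = np.random.default_rng(77)
        hits = 0
        for _ in range(50):
            x = rng.standard_normal(94)
            y = rng.poisson(np.exp(1.0 + 0.5 * x))
            counts = pd.Series(y, index=tree.tips)
            fit = fit_poisson_pglm(
                counts, pd.DataFrame({"x": x}, index=tree.tips), tree
            )
            hits += fit.beta["x"] > 0
        assert hits >= 48

    def test_all_zero_counts(self):
        tree = generate_tree(10, 1)
        counts = pd.Series(0, index=tree.tips)
        with pytest.raises(ValueError, match="degenerate"):
            fit_poisson_pglm(counts, pd.DataFrame(index=tree.tips), tree)

    def test_non_integer_counts(self):
        tree = generate_tree(10, 1)
        counts = pd.Series(1.5, index=tree.tips)
        with pytest.raises(ValueError, match="integer"):
            fit_poisson_pglm(counts, pd.DataFrame(index=tree.tips), tree)
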