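"""Lasso / adaptive lasso / OLS refit tests against independent oracles:
a hand-written coordinate-descent solver, normal equations, and the KKT
optimality conditions."""

import numpy as np
import pytest

from lassobags import (Dataset, fit_adaptive_lasso_cv, fit_lasso,
                       fit_lasso_cv, initial_weights, predict, refit_ols)

from conftest import make_dataset


def cd_lasso_oracle(X, y, lam, w=None, iters=20_000, tol=1e-12):
    """Brute-force cyclic coordinate descent for
    ||y - Xb||^2 + lam * sum_j w_j |b_j| (independent of the package)."""
    n, p = X.shape
    w = np.ones(p) if w is None else np.asarray(w, float)
    b = np.zeros(p)
    col_ss = (X**2).sum(axis=0)
    r = y.copy()
    for _ in range(iters):
        b_old = b.copy()
        for j in range(p):
            if col_ss[j] == 0:
                continue
            rho = X[:, j] @ r + col_ss[j] * b[j]
            thr = lam * w[j] / 2.0
            bj = np.sign(rho) * max(abs(rho) - thr, 0.0) / col_ss[j]
            r += X[:, j] * (b[j] - bj)
            b[j] = bj
        if np.max(np.abs(b - b_old)) < tol:
            break
    return b


def lasso_objective(X, y, b, lam, w=None):
    w = np.ones(X.shape[1]) if w is None else w
    r = y - X @ b
    return r @ r + lam * np.sum(w * np.abs(b))


class TestFitLasso:
    def test_full_shrinkage_above_lambda_max(self, toy_dataset):
        d = toy_dataset
        lam_max = 2.0 * np.max(np.abs(d.X.T @ d.y))
        sel = fit_lasso(d, lam_max * 1.01)
        assert sel.selected == []

    def test_zero_penalty_equals_ols(self, rng):
        X = rng.standard_normal((20, 2))
        y = rng.standard_normal(20)
        d = make_dataset(X, y, standardize=False)
        sel = fit_lasso(d, 0.0)
        A = np.column_stack([np.ones(20), X])
        ref = np.linalg.lstsq(A, y, rcond=None)[0]
        coef = np.zeros(2)
        for v, c in sel.coef_map().items():
            coef[d.column_index(v)] = c
        assert np.allclose(coef, ref[1:], atol=1e-8)

    def test_matches_coordinate_descent_oracle(self, rng):
        X = rng.standard_normal((20, 10))
        y = X[:, 0] - 0.5 * X[:, 3] + 0.2 * rng.standard_normal(20)
        d = make_dataset(X, y)
        lam = 4.0
        sel = fit_lasso(d, lam)
        beta = np.zeros(10)
        for v, c in sel.coef_map().items():
            beta[d.column_index(v)] = c
        oracle = cd_lasso_oracle(d.X, d.y, lam)
        assert np.allclose(beta, oracle, atol=1e-6)
        # local optimality against random perturbations
        obj = lasso_objective(d.X, d.y, beta, lam)
        for _ in range(1000):
            pert = beta + rng.normal(0, 0.01, size=10)
            assert obj <= lasso_objective(d.X, d.y, pert, lam) + 1e-12

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_cv_solution_satisfies_kkt(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((40, 25))
        y = X[:, 0] - X[:, 1] + 0.5 * rng.standard_normal(40)
        d = make_dataset(X, y)
        sel = fit_lasso_cv(d, k=5, seed=seed)
        beta = np.zeros(25)
        for v, c in sel.coef_map().items():
            beta[d.column_index(v)] = c
        r = d.y - d.X @ beta - sel.intercept
        grad = 2.0 * (d.X.T @ r)  # = lam * sign(b_j) on the active set
        scale = max(1.0, sel.lambda_)
        for j in range(25):
            if beta[j] == 0:
                assert abs(grad[j]) <= sel.lambda_ + 1e-6 * scale
            else:
                assert grad[j] == pytest.approx(sel.lambda_ * np.sign(beta[j]),
                                                abs=1e-6 * scale)

    def test_cv_deterministic_under_fold_seed(self, toy_dataset):
        a = fit_lasso_cv(toy_dataset, k=5, seed=42)
        b = fit_lasso_cv(toy_dataset, k=5, seed=42)
        assert a.selected == b.selected
        assert np.array_equal(a.coefficients, b.coefficients)
        assert a.lambda_ == b.lambda_

    def test_constant_response_warns_empty(self, rng):
        X = rng.standard_normal((20, 5))
        d = make_dataset(X, np.zeros(20), standardize=False)
        with pytest.warns(UserWarning, match="constant"):
            sel = fit_lasso_cv(d, k=4, seed=0)
        assert sel.selected == []


class TestInitialWeights:
    def test_reciprocal_of_marginal_ols(self, rng):
        X = rng.standard_normal((50, 4))
        y = rng.standard_normal(50)
        d = make_dataset(X, y)
        w = initial_weights(d, "marginal_ols")
        Xc = d.X - d.X.mean(0)
        yc = d.y - d.y.mean()
        b = np.array([Xc[:, j] @ yc / (Xc[:, j] @ Xc[:, j]) for j in range(4)])
        assert np.allclose(w, 1.0 / np.abs(b))

    def test_zero_initial_coefficient_gives_infinite_weight(self, rng):
        X = rng.standard_normal((30, 3))
        y = X[:, 0] + 0.1 * rng.standard_normal(30)
        X[:, 2] = 1.0  # constant column: marginal OLS slope exactly 0
        d = Dataset(X, y, ["x1", "x2", "x3"])
        w = initial_weights(d, "marginal_ols")
        assert np.isinf(w[2])
        sel = fit_adaptive_lasso_cv(d, k=3, weights=w, seed=0)
        assert "x3" not in sel.selected

    def test_ols_scheme_requires_more_rows_than_columns(self, rng):
        d = make_dataset(rng.standard_normal((5, 8)), rng.standard_normal(5))
        with pytest.raises(ValueError, match="marginal_ols"):
            initial_weights(d, "ols")

    def test_lasso_init_excludes_dropped_variables(self, small_sim_config):
        from lassobags import simulate_dataset

        data, _, _ = simulate_dataset(small_sim_config)
        w = initial_weights(data, "lasso_init", seed=0)
        base = fit_lasso_cv(data, k=5, seed=0)
        dropped = set(data.var_ids) - set(base.selected)
        assert all(np.isinf(w[data.column_index(v)]) for v in dropped)


class TestAdaptiveLasso:
    def test_unit_weights_reduce_to_plain_lasso(self, toy_dataset):
        plain = fit_lasso_cv(toy_dataset, k=5, seed=3)
        adapt = fit_adaptive_lasso_cv(toy_dataset, k=5,
                                      weights=np.ones(toy_dataset.p), seed=3)
        assert adapt.selected == plain.selected
        assert np.allclose(adapt.coefficients, plain.coefficients, atol=1e-10)

    def test_constant_weights_equal_plain_lasso(self, toy_dataset):
        plain = fit_lasso_cv(toy_dataset, k=5, seed=3)
        adapt = fit_adaptive_lasso_cv(toy_dataset, k=5,
                                      weights=np.full(toy_dataset.p, 3.0), seed=3)
        assert adapt.selected == plain.selected
        assert np.allclose(adapt.coefficients, plain.coefficients, atol=1e-8)

    def test_huge_weight_matches_reduced_design(self, rng):
        X = rng.standard_normal((40, 5))
        y = X[:, 0] + 0.3 * rng.standard_normal(40)
        d = make_dataset(X, y)
        w = np.ones(5)
        w[4] = np.inf
        full = fit_adaptive_lasso_cv(d, k=5, weights=w, seed=1)
        reduced = make_dataset(X[:, :4], y)
        ref = fit_lasso_cv(reduced, k=5, seed=1)
        assert "x5" not in full.selected
        assert full.selected == ref.selected
        assert np.allclose(full.coefficients, ref.coefficients, atol=1e-8)

    def test_all_infinite_weights_empty_model(self, toy_dataset):
        with pytest.warns(UserWarning, match="infinite"):
            sel = fit_adaptive_lasso_cv(toy_dataset, k=5,
                                        weights=np.full(toy_dataset.p, np.inf), seed=0)
        assert sel.selected == []

    def test_weighted_solution_matches_cd_oracle(self, rng):
        X = rng.standard_normal((25, 8))
        y = X[:, 1] + 0.2 * rng.standard_normal(25)
        d = make_dataset(X, y)
        w = rng.uniform(0.5, 2.0, size=8)
        lam = 3.0
        sel = fit_lasso(d, lam, weights=w)
        beta = np.zeros(8)
        for v, c in sel.coef_map().items():
            beta[d.column_index(v)] = c
        oracle = cd_lasso_oracle(d.X, d.y, lam, w)
        assert np.allclose(beta, oracle, atol=1e-6)


class TestRefitOls:
    def test_empty_set_predicts_mean(self, toy_dataset):
        m = refit_ols([], toy_dataset)
        assert m.variables == []
        assert m.intercept == pytest.approx(float(toy_dataset.y.mean()))
        assert np.allclose(predict(m, toy_dataset), toy_dataset.y.mean())

    def test_single_standardized_variable(self, toy_dataset):
        m = refit_ols(["x1"], toy_dataset)
        x = toy_dataset.columns(["x1"])[:, 0]
        y = toy_dataset.y
        expected = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert m.coefficients[0] == pytest.approx(expected)

    def test_matches_normal_equations(self, rng):
        X = rng.standard_normal((10, 3))
        y = rng.standard_normal(10)
        d = make_dataset(X, y, standardize=False)
        m = refit_ols(["x1", "x2", "x3"], d)
        A = np.column_stack([np.ones(10), X])
        ref = np.linalg.solve(A.T @ A, A.T @ y)
        assert m.intercept == pytest.approx(ref[0], abs=1e-10)
        assert np.allclose(m.coefficients, ref[1:], atol=1e-10)

    def test_residuals_orthogonal_to_design(self, toy_dataset):
        m = refit_ols(["x1", "x2", "x3"], toy_dataset)
        r = toy_dataset.y - predict(m, toy_dataset)
        assert np.allclose(toy_dataset.columns(m.variables).T @ r, 0, atol=1e-9)

    def test_collinear_column_dropped_with_warning(self, rng):
        X = rng.standard_normal((15, 2))
        X = np.column_stack([X, X[:, 0]])  # x3 duplicates x1
        y = rng.standard_normal(15)
        d = make_dataset(X, y, standardize=False)
        with pytest.warns(UserWarning, match="collinear"):
            m = refit_ols(["x1", "x2", "x3"], d)
        assert m.variables == ["x1", "x2"]
        assert m.dropped == ["x3"]

    def test_too_many_variables_rejected(self, rng):
        d = make_dataset(rng.standard_normal((4, 6)), rng.standard_normal(4))
        with pytest.raises(ValueError, match="ill-posed"):
            refit_ols(["x1", "x2", "x3", "x4"], d)


class TestPredict:
    def test_manual_three_sample_example(self):
        from lassobags import FinalModel

        d = Dataset(np.array([[1.0, 2.0], [0.0, -1.0], [2.0, 0.5]]),
                    np.zeros(3), ["a", "b"])
        m = FinalModel(["a", "b"], np.array([2.0, -1.0]), 0.5)
        assert np.allclose(predict(m, d), [0.5 + 2 - 2, 0.5 + 0 + 1, 0.5 + 4 - 0.5])

    def test_missing_variable_raises(self, toy_dataset):
        from lassobags import FinalModel

        m = FinalModel(["nope"], np.array([1.0]), 0.0)
        with pytest.raises(KeyError, match="nope"):
            predict(m, toy_dataset)
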