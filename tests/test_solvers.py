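"""Core solver checks: standardization, augmented design, exact solve,
coordinate descent, and the algebraic reductions of the two-level model."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from hierridge import (
    HierarchicalRidge,
    PenaltyPair,
    build_augmented,
    gradient,
    objective_value,
    solve_cd,
    solve_closed_form,
    standardize,
)

from conftest import random_instance


class TestStandardize:
    def test_column_mean_zero_variance_one(self):
        fd = standardize(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 9.0]]))
        assert np.allclose(fd.X.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(fd.X.var(axis=0), 1, atol=1e-12)

    def test_idempotent(self, rng):
        X = rng.standard_normal((20, 4))
        once = standardize(X).X
        twice = standardize(once).X
        assert np.allclose(once, twice, atol=1e-12)

    def test_constant_column_rejected_with_index(self):
        X = np.ones((5, 3))
        X[:, 0] = np.arange(5)
        X[:, 2] = np.arange(5) ** 2
        with pytest.raises(ValueError, match=r"zero variance.*\[1\]"):
            standardize(X)

    def test_y_centering_stores_mean(self, rng):
        X = rng.standard_normal((10, 2))
        y = rng.standard_normal(10) + 5.0
        fd = standardize(X, y)
        assert fd.y_mean == pytest.approx(5.0, abs=1.0)
        assert fd.y.mean() == pytest.approx(0.0, abs=1e-12)

    def test_transform_applies_training_statistics(self, rng):
        X = rng.standard_normal((15, 3)) * 4 + 2
        fd = standardize(X)
        Xn = rng.standard_normal((6, 3))
        assert np.allclose(fd.transform(Xn), (Xn - fd.column_means) / fd.column_scales)
        with pytest.raises(ValueError, match="columns"):
            fd.transform(np.ones((3, 5)))


class TestAugmentedDesign:
    def test_identity_X(self):
        Xt = build_augmented(np.eye(2), np.array([[1.0], [1.0]]))
        assert np.allclose(Xt[:, 2], [1.0, 1.0])

    def test_empty_meta_returns_X(self, rng):
        X = rng.standard_normal((4, 3))
        assert build_augmented(X, None) is X
        assert build_augmented(X, np.empty((3, 0))) is X

    def test_block_columns_are_matrix_products(self, rng):
        X = rng.standard_normal((5, 4))
        Z = rng.standard_normal((4, 2))
        Xt = build_augmented(X, Z)
        assert Xt.shape == (5, 6)
        for j in range(2):
            assert np.allclose(Xt[:, 4 + j], X @ Z[:, j])

    def test_dimension_mismatch_reports_shapes(self, rng):
        with pytest.raises(ValueError, match=r"\(5, 4\).*\(3, 2\)"):
            build_augmented(rng.standard_normal((5, 4)), rng.standard_normal((3, 2)))

    def test_sparse_times_sparse_stays_sparse(self):
        X = sp.random(30, 40, density=0.05, random_state=0, format="csr")
        Z = sp.random(40, 6, density=0.1, random_state=1, format="csr")
        Xt = build_augmented(X, Z)
        assert sp.issparse(Xt)
        assert np.allclose(Xt.toarray(), np.hstack([X.toarray(), (X @ Z).toarray()]))


class TestClosedForm:
    def test_zero_meta_matrix_reduces_to_standard_ridge(self, rng):
        X, _, y, l1, _ = random_instance(rng, n=25, p=8, q=3)
        Z0 = np.zeros((8, 3))
        m = HierarchicalRidge(y, X, Z0)
        res = m.fit(l1, 7.0)
        ridge = HierarchicalRidge(y, X).fit(l1)
        assert np.allclose(res.beta, ridge.beta, atol=1e-10)
        assert np.allclose(res.gamma, 0, atol=1e-10)

    def test_equal_penalties_match_single_lambda_ridge_on_augmented(self, rng):
        X, Z, y, _, _ = random_instance(rng, n=30, p=6, q=2)
        m = HierarchicalRidge(y, X, Z)
        res = m.fit(3.0, 3.0)
        Xt = build_augmented(m.data.X, Z)
        theta = solve_closed_form(Xt, m.data.y, np.full(8, 3.0))
        assert np.allclose(np.r_[res.phi, res.gamma], theta, atol=1e-12)

    def test_orthonormal_shrinkage_identity(self, rng):
        # with X'X = I and no meta-features, ridge = OLS / (1 + lambda)
        from hierridge.oracles import orthonormal_design

        X = orthonormal_design(40, 6, rng)
        y = rng.standard_normal(40)
        lam = 2.5
        theta = solve_closed_form(X, y, np.full(6, lam))
        assert np.allclose(theta, (X.T @ y) / (1 + lam), atol=1e-12)

    def test_lambda2_inf_sentinel_matches_huge_lambda2(self, rng):
        X, Z, y, _, _ = random_instance(rng, n=25, p=10, q=3)
        m = HierarchicalRidge(y, X, Z)
        huge = m.fit(2.0, 1e8)
        ridge = m.fit(2.0, np.inf)
        assert np.max(np.abs(huge.beta - ridge.beta)) <= 1e-4
        assert ridge.gamma.size == 0

    def test_dual_and_primal_routes_agree(self, rng):
        X = rng.standard_normal((12, 40))
        y = rng.standard_normal(12)
        lamvec = np.full(40, 0.7)
        dual = solve_closed_form(X, y, lamvec)  # m > n
        direct = np.linalg.solve(X.T @ X + np.diag(lamvec), X.T @ y)
        assert np.allclose(dual, direct, atol=1e-10)

    def test_weighted_solve(self, rng):
        X = rng.standard_normal((20, 5))
        y = rng.standard_normal(20)
        w = rng.uniform(0.5, 2.0, 20)
        lamvec = np.full(5, 1.3)
        theta = solve_closed_form(X, y, lamvec, weights=w)
        direct = np.linalg.solve((X * w[:, None]).T @ X + np.diag(lamvec),
                                 X.T @ (w * y))
        assert np.allclose(theta, direct, atol=1e-10)

    def test_input_validation(self, rng):
        X = rng.standard_normal((10, 3))
        y = rng.standard_normal(10)
        with pytest.raises(ValueError, match="non-finite"):
            solve_closed_form(X, np.r_[y[:-1], np.nan], np.ones(3))
        with pytest.raises(ValueError, match="finite and > 0"):
            solve_closed_form(X, y, np.array([1.0, 0.0, 1.0]))
        with pytest.raises(ValueError):
            PenaltyPair(-1.0, 2.0)
        with pytest.raises(ValueError):
            PenaltyPair(1.0, 0.0)


class TestCoordinateDescent:
    @pytest.mark.parametrize("use_gram", [True, False])
    @pytest.mark.parametrize("shape", [(20, 5, 2), (15, 25, 4), (40, 10, 8)])
    def test_matches_closed_form(self, rng, shape, use_gram):
        n, p, q = shape
        X, Z, y, l1, l2 = random_instance(rng, n=n, p=p, q=q)
        Xt = build_augmented(X, Z)
        lamvec = np.r_[np.full(p, l1), np.full(q, l2)]
        exact = solve_closed_form(Xt, y, lamvec)
        info = solve_cd(Xt, y, lamvec, tol=1e-9, max_sweeps=30000, use_gram=use_gram)
        assert info.converged
        assert np.max(np.abs(info.theta - exact)) < 1e-6

    def test_objective_nonincreasing_and_gradient_stationary(self, rng):
        X, Z, y, l1, l2 = random_instance(rng, n=30, p=12, q=4)
        Xt = build_augmented(X, Z)
        lamvec = np.r_[np.full(12, l1), np.full(4, l2)]
        info = solve_cd(Xt, y, lamvec, tol=1e-9, max_sweeps=30000)
        assert np.all(np.diff(info.objective_path) <= 1e-10)
        g = gradient(Xt, y, info.theta, lamvec)
        assert np.max(np.abs(g)) < 1e-6

    def test_warm_start_at_solution_converges_in_one_sweep(self, rng):
        X, Z, y, l1, l2 = random_instance(rng, n=20, p=6, q=2)
        Xt = build_augmented(X, Z)
        lamvec = np.r_[np.full(6, l1), np.full(2, l2)]
        exact = solve_closed_form(Xt, y, lamvec)
        info = solve_cd(Xt, y, lamvec, theta0=exact, tol=1e-7)
        assert info.converged and info.n_iter == 1

    def test_warm_and_cold_starts_reach_same_solutions_along_path(self, rng):
        X, Z, y, _, _ = random_instance(rng, n=25, p=8, q=3)
        Xt = build_augmented(X, Z)
        path = np.geomspace(100, 0.1, 6)
        warm = None
        for lam in path:
            lamvec = np.r_[np.full(8, lam), np.full(3, lam * 2)]
            cold = solve_cd(Xt, y, lamvec, tol=1e-9, max_sweeps=30000)
            warm = solve_cd(Xt, y, lamvec, theta0=warm, tol=1e-9, max_sweeps=30000)
            assert np.max(np.abs(cold.theta - warm.theta)) < 1e-6
            warm = warm.theta

    def test_infinite_shrinkage_limit(self, rng):
        X, Z, y, _, _ = random_instance(rng, n=20, p=5, q=2)
        Xt = build_augmented(X, Z)
        info = solve_cd(Xt, y, np.full(7, 1e10), tol=1e-12)
        assert np.max(np.abs(info.theta)) < 1e-6

    def test_nonconvergence_warns_and_flags(self, rng):
        X, Z, y, _, _ = random_instance(rng, n=20, p=10, q=3)
        Xt = build_augmented(X, Z)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            info = solve_cd(Xt, y, np.full(13, 0.1), tol=1e-14, max_sweeps=2)
        assert not info.converged

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_routes_agree_property(self, seed):
        rng = np.random.default_rng(seed)
        X, Z, y, l1, l2 = random_instance(rng)
        p, q = Z.shape
        Xt = build_augmented(X, Z)
        lamvec = np.r_[np.full(p, l1), np.full(q, l2)]
        exact = solve_closed_form(Xt, y, lamvec)
        info = solve_cd(Xt, y, lamvec, tol=1e-9, max_sweeps=30000)
        assert np.max(np.abs(info.theta - exact)) < 1e-6
        # objective at the CD solution cannot beat the exact minimizer
        assert objective_value(Xt, y, info.theta, lamvec) >= objective_value(
            Xt, y, exact, lamvec
        ) - 1e-9


class TestPredict:
    def test_in_sample_fitted_values(self, rng):
        X, Z, y, l1, l2 = random_instance(rng, n=25, p=6, q=2)
        m = HierarchicalRidge(y, X, Z)
        res = m.fit(l1, l2)
        assert np.allclose(res.predict(X), res.fittedvalues, atol=1e-12)

    def test_null_coefficients_predict_intercept(self, rng):
        X, Z, y, _, _ = random_instance(rng, n=25, p=6, q=2)
        m = HierarchicalRidge(y, X, Z)
        res = m.fit(1e12, 1e12)
        assert np.allclose(res.predict(X), np.mean(y), atol=1e-6)

    def test_beta_and_theta_routes_identical(self, rng):
        X, Z, y, l1, l2 = random_instance(rng, n=25, p=7, q=3)
        m = HierarchicalRidge(y, X, Z)
        res = m.fit(l1, l2)
        Xn = rng.standard_normal((8, 7))
        Xs = m.data.transform(Xn)
        via_beta = res.intercept + Xs @ res.beta
        via_theta = res.intercept + build_augmented(Xs, Z) @ np.r_[res.phi, res.gamma]
        assert np.max(np.abs(via_beta - via_theta)) < 1e-10
        assert np.allclose(res.predict(Xn), via_beta)

    def test_column_count_mismatch(self, rng):
        X, Z, y, l1, l2 = random_instance(rng, n=20, p=6, q=2)
        res = HierarchicalRidge(y, X, Z).fit(l1, l2)
        with pytest.raises(ValueError, match="columns"):
            res.predict(rng.standard_normal((4, 5)))
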