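"""Tests for the penalized-GLM coordinate descent / IRLS core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from sklearn.linear_model import Lasso, LogisticRegression

from phylosparse import phylo, solver
from tests.conftest import brute_force_objective


class TestStandardize:
    def test_three_point_column(self):
        d = solver.standardize(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(d.X.ravel(),
                                   np.array([-1, 0, 1]) * np.sqrt(1.5))
        assert np.sum(d.X**2) == pytest.approx(3.0)

    def test_idempotent(self, rng):
        X = rng.normal(size=(30, 4))
        d1 = solver.standardize(X)
        d2 = solver.standardize(d1.X)
        np.testing.assert_allclose(d1.X, d2.X, atol=1e-12)

    def test_columns_centered_and_scaled(self, rng):
        X = rng.normal(size=(40, 7)) * 3 + 5
        d = solver.standardize(X)
        np.testing.assert_allclose(d.X.sum(axis=0), 0, atol=1e-8)
        np.testing.assert_allclose((d.X**2).sum(axis=0), 40, atol=1e-8)

    def test_constant_column_error_names_offenders(self):
        X = np.column_stack([np.arange(5.0), np.ones(5)])
        with pytest.raises(ValueError, match="otuB"):
            solver.standardize(X, column_ids=["otuA", "otuB"])


class TestMCPPenalty:
    def test_closed_form_values(self):
        assert solver.mcp_penalty(0.0, 1.0, 3.0) == 0.0
        assert solver.mcp_penalty(1.0, 1.0, 3.0) == pytest.approx(1 - 1 / 6)
        # saturation at gamma*lambda^2/2 beyond gamma*lambda
        assert solver.mcp_penalty(5.0, 1.0, 3.0) == pytest.approx(1.5)
        assert solver.mcp_penalty(50.0, 1.0, 3.0) == pytest.approx(1.5)

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            solver.mcp_penalty(1.0, 1.0, 0.9)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-20, 20), st.floats(0.01, 2), st.floats(1.5, 50))
    def test_matches_numerical_integral(self, t, lam1, gamma):
        """rho(t) = lam1 * int_0^|t| (1 - x/(gamma lam1))_+ dx."""
        xs = np.linspace(0, abs(t), 4001)
        integrand = lam1 * np.clip(1 - xs / (gamma * lam1), 0, None)
        expected = np.trapezoid(integrand, xs)
        assert solver.mcp_penalty(t, lam1, gamma) == pytest.approx(
            expected, abs=1e-4, rel=1e-4)


class TestQuadraticPenalty:
    def test_trivial_cases(self):
        assert solver.quadratic_penalty(np.zeros(4), np.eye(4), 2.0) == 0.0
        assert solver.quadratic_penalty(np.array([1.0, 2.0]), np.eye(2), 1.0) \
            == pytest.approx(5.0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            solver.quadratic_penalty(np.ones(3), np.eye(4), 1.0)

    def test_decomposes_into_weighted_l2_plus_laplacian(self, rng):
        """beta' Omega beta splits into a weighted ridge part and a
        sign-adjusted Laplacian part with adjacency |Omega_jk|."""
        for _ in range(20):
            p = 6
            A = rng.normal(size=(p, p))
            Omega = A @ A.T + p * np.eye(p)
            beta = rng.normal(size=p)
            direct = solver.quadratic_penalty(beta, Omega, 1.0)
            ridge = sum(
                (Omega[i, i] - sum(abs(Omega[i, j]) for j in range(p) if j != i))
                * beta[i] ** 2 for i in range(p)
            )
            lap = sum(
                abs(Omega[j, k]) * (beta[j] - np.sign(-Omega[j, k]) * beta[k]) ** 2
                for j in range(p) for k in range(j + 1, p)
            )
            assert direct == pytest.approx(ridge + lap, abs=1e-10)


class TestScalarUpdate:
    def test_soft_threshold_dead_zone(self):
        assert solver.scalar_update(1.0, 0.5, 1.0, 3.0) == 0.0

    @pytest.mark.parametrize("a,b,lam1,gamma", [
        (1.0, 2.0, 1.0, 3.0),
        (1.0, 4.0, 1.0, 3.0),
        (1.7, -2.5, 0.4, 2.5),
        (0.9, 1.1, 0.3, 8.0),
    ])
    def test_matches_dense_grid_search(self, a, b, lam1, gamma):
        ts = np.arange(-10, 10, 1e-4)
        obj = 0.5 * a * ts**2 - b * ts + solver.mcp_penalty(ts, lam1, gamma)
        t_grid = ts[np.argmin(obj)]
        assert solver.scalar_update(a, b, lam1, gamma) == pytest.approx(
            t_grid, abs=2e-4)

    def test_known_values(self):
        assert solver.scalar_update(1.0, 2.0, 1.0, 3.0) == pytest.approx(1.5)
        assert solver.scalar_update(1.0, 4.0, 1.0, 3.0) == pytest.approx(4.0)

    def test_nonconvex_subproblem_is_error(self):
        with pytest.raises(ValueError, match="gamma"):
            solver.scalar_update(0.2, 1.0, 1.0, 3.0)


class TestPenalizedObjective:
    def test_null_linear_model_is_half_variance(self, rng):
        y = rng.normal(size=20)
        X = rng.normal(size=(20, 3))
        d = solver.standardize(X)
        spec = solver.PenaltySpec(lambda1=0.5, gamma=3.0)
        obj = solver.penalized_objective(y.mean(), np.zeros(3), d, y,
                                         "linear", spec)
        assert obj == pytest.approx(0.5 * np.mean((y - y.mean()) ** 2))

    def test_null_logistic_model_is_log2(self, rng):
        y = (rng.random(20) > 0.5).astype(float)
        d = solver.standardize(rng.normal(size=(20, 3)))
        spec = solver.PenaltySpec(lambda1=0.5, gamma=30.0)
        obj = solver.penalized_objective(0.0, np.zeros(3), d, y, "logistic",
                                         spec)
        assert obj == pytest.approx(np.log(2.0))

    def test_matches_naive_recomputation(self, rng):
        for family in ("linear", "logistic"):
            X = rng.normal(size=(25, 4))
            d = solver.standardize(X)
            y = (rng.normal(size=25) if family == "linear"
                 else (rng.random(25) > 0.4).astype(float))
            beta = rng.normal(size=4)
            b0 = rng.normal()
            A = rng.normal(size=(4, 4))
            S = A @ A.T
            spec = solver.PenaltySpec(lambda1=0.3, gamma=3.0, lambda2=0.7,
                                      structure=S)
            got = solver.penalized_objective(b0, beta, d, y, family, spec)
            want = brute_force_objective(b0, beta, d.X, y, family, 0.3, 3.0,
                                         0.7, S)
            assert got == pytest.approx(want, rel=1e-10)

    def test_bad_binary_outcome_is_error(self, rng):
        d = solver.standardize(rng.normal(size=(10, 2)))
        spec = solver.PenaltySpec(lambda1=0.1, gamma=30.0)
        with pytest.raises(ValueError, match="0, 1"):
            solver.penalized_objective(0.0, np.zeros(2), d, np.arange(10.0),
                                       "logistic", spec)


class TestFitLinear:
    def test_all_zero_above_lambda_max(self, small_linear_problem):
        X, y = small_linear_problem
        d = solver.standardize(X)
        lam_max = float(np.max(np.abs(d.X.T @ (y - y.mean()))) / len(y))
        spec = solver.PenaltySpec(lambda1=1.01 * lam_max, gamma=3.0)
        f = solver.fit(d, y, "linear", spec)
        np.testing.assert_allclose(f.beta_std, 0.0)
        assert f.intercept == pytest.approx(y.mean())

    def test_unpenalized_matches_ols(self, small_linear_problem):
        X, y = small_linear_problem
        d = solver.standardize(X)
        spec = solver.PenaltySpec(lambda1=0.0, gamma=3.0)
        f = solver.fit(d, y, "linear", spec, tol=1e-10, max_sweeps=20000)
        b_ols = np.linalg.solve(d.X.T @ d.X, d.X.T @ (y - y.mean()))
        np.testing.assert_allclose(f.beta_std, b_ols, atol=1e-6)

    def test_matches_general_purpose_optimizer(self, rng):
        n, p = 30, 4
        X = rng.normal(size=(n, p))
        d = solver.standardize(X)
        y = d.X @ np.array([1.0, -0.5, 0, 0]) + rng.normal(size=n)
        A = rng.normal(size=(p, p))
        S = A @ A.T + 0.5 * np.eye(p)
        spec = solver.PenaltySpec(lambda1=0.1, gamma=3.0, lambda2=0.5,
                                  structure=S)
        f = solver.fit(d, y, "linear", spec, tol=1e-9, max_sweeps=20000)
        obj_cd = solver.penalized_objective(f.intercept, f.beta_std, d, y,
                                            "linear", spec)

        def fun(z):
            return solver.penalized_objective(z[0], z[1:], d, y, "linear",
                                              spec)

        best = np.inf
        for start in (np.zeros(p + 1),
                      np.concatenate([[f.intercept], f.beta_std])):
            r = minimize(fun, start, method="Nelder-Mead",
                         options={"maxiter": 20000, "xatol": 1e-10,
                                  "fatol": 1e-12})
            best = min(best, r.fun)
        assert obj_cd <= best + 1e-5

        # local minimum against many random perturbations
        Z = rng.normal(size=(20000, p)) * 1e-3
        pert = f.beta_std[None, :] + Z
        res = (y - y.mean())[None, :] - pert @ d.X.T
        loss = 0.5 * np.mean(res**2, axis=1)
        pen1 = solver.mcp_penalty(pert, 0.1, 3.0).sum(axis=1)
        pen2 = 0.5 * np.einsum("ij,jk,ik->i", pert, S, pert)  # lambda2 = 0.5
        objs = loss + pen1 + pen2
        assert obj_cd <= objs.min() + 1e-10

    def test_objective_nonincreasing_per_sweep(self, rng):
        X = rng.normal(size=(40, 15))
        d = solver.standardize(X)
        y = d.X[:, 0] - d.X[:, 5] + rng.normal(size=40)
        A = rng.normal(size=(15, 15))
        spec = solver.PenaltySpec(lambda1=0.05, gamma=3.0, lambda2=0.2,
                                  structure=A @ A.T)
        f = solver.fit(d, y, "linear", spec)
        assert np.all(np.diff(f.objective_trace) <= 1e-12)

    def test_nonconvergence_flag(self, rng, caplog):
        X = rng.normal(size=(20, 30))
        d = solver.standardize(X)
        y = rng.normal(size=20)
        spec = solver.PenaltySpec(lambda1=0.001, gamma=3.0)
        f = solver.fit(d, y, "linear", spec, max_sweeps=1)
        assert not f.converged


class TestFitLogistic:
    def test_unpenalized_matches_sklearn(self, rng):
        X = rng.normal(size=(80, 6))
        eta = X @ np.array([1.5, -1, 0, 0, 0, 0.5])
        y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        d = solver.standardize(X)
        spec = solver.PenaltySpec(lambda1=0.0, gamma=30.0)
        f = solver.fit(d, y, "logistic", spec, tol=1e-8)
        sk = LogisticRegression(C=1e8, max_iter=5000, tol=1e-10).fit(d.X, y)
        np.testing.assert_allclose(f.beta_std, sk.coef_.ravel(), atol=2e-3)
        assert f.intercept == pytest.approx(float(sk.intercept_[0]), abs=2e-3)

    def test_probability_half_at_zero_eta(self, rng):
        X = rng.normal(size=(40, 3))
        y = (rng.random(40) > 0.5).astype(float)
        d = solver.standardize(X)
        spec = solver.PenaltySpec(lambda1=10.0, gamma=30.0)
        f = solver.fit(d, y, "logistic", spec)
        np.testing.assert_allclose(f.beta_std, 0.0)
        pred = solver.predict(f, X)
        np.testing.assert_allclose(pred, y.mean(), atol=1e-6)


class TestReductions:
    """Special cases of the penalty recover Lasso / MCP / MCP+ridge (Mnet)."""

    def test_huge_gamma_recovers_lasso(self, rng):
        n, p = 60, 8
        X = rng.normal(size=(n, p))
        d = solver.standardize(X)
        y = d.X @ np.concatenate([[1.0, -1.0], np.zeros(p - 2)]) \
            + rng.normal(size=n)
        lam = 0.15
        spec = solver.PenaltySpec(lambda1=lam, gamma=1e6)
        f = solver.fit(d, y, "linear", spec, tol=1e-9, max_sweeps=20000)
        sk = Lasso(alpha=lam, fit_intercept=True, tol=1e-12,
                   max_iter=100000).fit(d.X, y)
        np.testing.assert_allclose(f.beta_std, sk.coef_, atol=1e-4)

    def test_identity_structure_equals_large_alpha_tree(self, rng):
        """alpha -> infinity collapses the tree penalty onto plain ridge."""
        n, p = 40, 10
        X = rng.normal(size=(n, p))
        d = solver.standardize(X)
        y = d.X[:, 0] + rng.normal(size=n)
        D = np.abs(rng.normal(size=(p, p))) + 0.01
        D = 0.5 * (D + D.T)
        np.fill_diagonal(D, 0.0)
        Omega_far = phylo.inverse_correlation(
            phylo.correlation_matrix(D, 1e6), alpha=1e6).Omega
        f_tree = solver.fit(d, y, "linear", solver.PenaltySpec(
            lambda1=0.1, gamma=3.0, lambda2=0.4, structure=Omega_far),
            tol=1e-9, max_sweeps=20000)
        f_id = solver.fit(d, y, "linear", solver.PenaltySpec(
            lambda1=0.1, gamma=3.0, lambda2=0.4, structure=np.eye(p)),
            tol=1e-9, max_sweeps=20000)
        np.testing.assert_allclose(f_tree.beta_std, f_id.beta_std, atol=1e-5)

    def test_mnet_matches_independent_optimizer(self, rng):
        n, p = 40, 5
        X = rng.normal(size=(n, p))
        d = solver.standardize(X)
        y = d.X @ np.array([1, 1, 0, 0, -1.0]) + rng.normal(size=n)
        spec = solver.PenaltySpec(lambda1=0.12, gamma=3.0, lambda2=0.3,
                                  structure=np.eye(p))
        f = solver.fit(d, y, "linear", spec, tol=1e-10, max_sweeps=50000)
        obj_cd = solver.penalized_objective(f.intercept, f.beta_std, d, y,
                                            "linear", spec)

        def fun(z):
            return solver.penalized_objective(z[0], z[1:], d, y, "linear",
                                              spec)

        r = minimize(fun, np.concatenate([[f.intercept], f.beta_std + 0.01]),
                     method="Nelder-Mead",
                     options={"maxiter": 50000, "xatol": 1e-10,
                              "fatol": 1e-13})
        assert obj_cd <= r.fun + 1e-5

    def test_no_rescaling_of_l2_shrinkage(self, rng):
        """The ridge-type shrinkage is deliberately left in: the raw solution
        minimizes the objective, a (1 + 2 lambda2)-rescaled variant does not."""
        n, p = 50, 4
        X = rng.normal(size=(n, p))
        d = solver.standardize(X)
        y = d.X @ np.array([2.0, -1.0, 0, 0]) + rng.normal(size=n)
        lam2 = 0.5
        spec = solver.PenaltySpec(lambda1=0.05, gamma=3.0, lambda2=lam2,
                                  structure=np.eye(p))
        f = solver.fit(d, y, "linear", spec, tol=1e-9)
        rescaled = f.beta_std * (1.0 + 2.0 * lam2)
        obj_raw = solver.penalized_objective(f.intercept, f.beta_std, d, y,
                                             "linear", spec)
        obj_rescaled = solver.penalized_objective(f.intercept, rescaled, d, y,
                                                  "linear", spec)
        assert obj_raw < obj_rescaled
        assert not np.allclose(f.beta_std, rescaled)


class TestFitPath:
    def test_single_element_equals_fit(self, small_linear_problem):
        X, y = small_linear_problem
        d = solver.standardize(X)
        path = solver.fit_path(d, y, "linear", np.array([0.2]), gamma=3.0)
        single = solver.fit(d, y, "linear",
                            solver.PenaltySpec(lambda1=0.2, gamma=3.0))
        np.testing.assert_allclose(path[0].beta_std, single.beta_std,
                                   atol=1e-10)

    def test_unsorted_sequence_is_error(self, small_linear_problem):
        X, y = small_linear_problem
        d = solver.standardize(X)
        with pytest.raises(ValueError, match="decreasing"):
            solver.fit_path(d, y, "linear", np.array([0.1, 0.2]))

    def test_warm_starts_match_cold_starts(self, rng):
        n, p = 50, 12
        X = rng.normal(size=(n, p))
        d = solver.standardize(X)
        y = d.X[:, 0] * 2 - d.X[:, 3] + rng.normal(size=n)
        lam_seq = np.exp(np.linspace(np.log(0.5), np.log(0.01), 12))
        warm = solver.fit_path(d, y, "linear", lam_seq, gamma=3.0, tol=1e-8)
        for lam, f in zip(lam_seq, warm):
            cold = solver.fit(d, y, "linear",
                              solver.PenaltySpec(lambda1=float(lam), gamma=3.0),
                              tol=1e-8)
            np.testing.assert_allclose(f.beta_std, cold.beta_std, atol=1e-5)

    def test_support_mostly_grows_along_path(self, rng):
        grow = 0
        total = 0
        for trial in range(5):
            n, p = 40, 15
            X = rng.normal(size=(n, p))
            d = solver.standardize(X)
            y = d.X @ np.concatenate([rng.normal(size=3), np.zeros(p - 3)]) \
                + rng.normal(size=n)
            lam_max = float(np.max(np.abs(d.X.T @ (y - y.mean()))) / n)
            lam_seq = np.exp(np.linspace(np.log(lam_max), np.log(0.01 * lam_max), 20))
            fits = solver.fit_path(d, y, "linear", lam_seq, gamma=3.0)
            nnz = [f.nonzero.size for f in fits]
            grow += int(np.sum(np.diff(nnz) >= 0))
            total += len(nnz) - 1
        assert grow / total >= 0.9


class TestPredict:
    def test_constant_prediction_for_null_model(self, small_linear_problem):
        X, y = small_linear_problem
        d = solver.standardize(X)
        f = solver.fit(d, y, "linear",
                       solver.PenaltySpec(lambda1=100.0, gamma=3.0))
        np.testing.assert_allclose(solver.predict(f, X), y.mean(), atol=1e-10)

    def test_in_sample_consistency(self, small_linear_problem):
        X, y = small_linear_problem
        d = solver.standardize(X)
        f = solver.fit(d, y, "linear",
                       solver.PenaltySpec(lambda1=0.05, gamma=3.0))
        in_sample = f.intercept + d.X @ f.beta_std
        np.testing.assert_allclose(solver.predict(f, X), in_sample, atol=1e-8)

    def test_column_mismatch_is_error(self, small_linear_problem):
        X, y = small_linear_problem
        d = solver.standardize(X)
        f = solver.fit(d, y, "linear",
                       solver.PenaltySpec(lambda1=0.05, gamma=3.0))
        with pytest.raises(ValueError, match="columns"):
            solver.predict(f, X[:, :3])


class TestGroupingProperty:
    def test_within_clique_bound_small_case(self, rng, clique_tools):
        make_omega, xi_fn = clique_tools
        sizes = [3, 4]
        kappas = [1.5, 2.0]
        om0s = [1.0, 0.7]
        Om = make_omega(sizes, kappas, om0s)
        p = Om.shape[0]
        n = 30
        X = rng.normal(size=(n, p))
        d = solver.standardize(X)
        y = rng.normal(size=n)
        lam1, lam2, gamma = 0.1, 0.8, 3.0
        f = solver.fit(d, y, "linear",
                       solver.PenaltySpec(lambda1=lam1, gamma=gamma,
                                          lambda2=lam2, structure=Om),
                       tol=1e-8, max_sweeps=20000)
        start = 0
        for v, k, o in zip(sizes, kappas, om0s):
            t = 2 * lam2 * k * (v - 1) * o
            xi = xi_fn(t, gamma)
            idx = list(range(start, start + v))
            start += v
            for a in idx:
                for b in idx:
                    if a >= b:
                        continue
                    rho = float(d.X[:, a] @ d.X[:, b] / n)
                    bound = xi * np.sum(np.abs(y)) / n * np.sqrt(2 * (1 - rho))
                    assert abs(f.beta_std[a] - f.beta_std[b]) <= bound + 1e-10
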