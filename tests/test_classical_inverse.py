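"""Classical solvers: Tikhonov, modified TSVD, total variation."""

import numpy as np
import pytest
from scipy.optimize import minimize

from egminv import (
    GridSpec,
    ObservationField,
    SourceField,
    TransferOperator,
    build_regularizer,
    build_transfer_matrix,
    forward,
    tikhonov_solve,
    tsvd_solve,
    tv_solve,
)
from egminv.exceptions import ConfigurationError, ParameterError


def toy_operator(H, grid=None):
    """Wrap an explicit matrix as a TransferOperator for solver tests."""
    n = H.shape[0]
    grid = grid or GridSpec(dimension=1, length_cm=3.0, density=n / 3.0)
    T = TransferOperator(impulse=np.zeros(2 * n - 1), matrix=np.asarray(H, float),
                         grid=grid, constants=None)
    return T


def toy_obs(values, grid):
    obs = ObservationField.__new__(ObservationField)
    obs.values = np.asarray(values, float)
    obs.grid = grid
    return obs


class TestRegularizer:
    def test_order0_identity(self):
        R = build_regularizer(0, 3).matrix
        np.testing.assert_array_equal(R, np.eye(3))

    def test_order1_first_difference_rows(self):
        R = build_regularizer(1, 3).matrix
        np.testing.assert_array_equal(R, [[-1, 1, 0], [0, -1, 1]])

    def test_order2_second_difference_row(self):
        R = build_regularizer(2, 3).matrix
        np.testing.assert_array_equal(R, [[-1, 2, -1]])

    def test_2d_stacked_axes(self):
        R = build_regularizer(1, 3, dimension=2).matrix
        assert R.shape == (12, 9)  # 2 x (n-1) x n rows stacked for both axes
        v = np.arange(9.0)
        # constant image has zero derivative in both axes
        assert np.allclose(R @ np.ones(9), 0)
        assert not np.allclose(R @ v, 0)

    def test_invalid_order(self):
        with pytest.raises(ConfigurationError):
            build_regularizer(3, 5)


class TestTikhonov:
    def test_identity_operator_closed_form(self):
        n = 8
        T = toy_operator(np.eye(n))
        y = np.linspace(-2, 3, n)
        obs = toy_obs(y, T.grid)
        reg = build_regularizer(0, n)
        for gamma in (0.0, 0.5, 2.0):
            sol = tikhonov_solve(T, obs, gamma, reg)
            np.testing.assert_allclose(sol.estimate.values, y / (1 + gamma**2),
                                       rtol=1e-12)

    def test_gamma_zero_reduces_to_least_squares(self, rng):
        H = rng.standard_normal((4, 4)) + 4 * np.eye(4)
        T = toy_operator(H)
        y = rng.standard_normal(4)
        sol = tikhonov_solve(T, toy_obs(y, T.grid), 0.0, build_regularizer(0, 4))
        np.testing.assert_allclose(sol.estimate.values, np.linalg.solve(H, y),
                                   rtol=1e-10, atol=1e-10)

    @pytest.mark.parametrize("order", [0, 1, 2])
    def test_matches_generic_optimizer(self, order, rng):
        """Closed form equals brute-force minimization of the objective."""
        n = 3
        H = rng.standard_normal((n, n)) + 2 * np.eye(n)
        y = rng.standard_normal(n)
        gamma = 0.7
        T = toy_operator(H)
        reg = build_regularizer(order, n)
        R = reg.matrix

        def objective(v):
            return (np.sum((y - H @ v) ** 2)
                    + gamma**2 * np.sum((R @ v) ** 2))

        res = minimize(objective, np.zeros(n), method="BFGS",
                       options={"gtol": 1e-12})
        sol = tikhonov_solve(T, toy_obs(y, T.grid), gamma, reg)
        np.testing.assert_allclose(sol.estimate.values, res.x,
                                   rtol=1e-6, atol=1e-6)

    def test_solution_norm_monotone_in_gamma(self, model64):
        _, _, T, obs = model64
        reg = build_regularizer(0, T.grid.n_axis)
        norms, resids = [], []
        for gamma in np.geomspace(1e-2, 1e5, 10):
            sol = tikhonov_solve(T, obs, gamma, reg)
            norms.append(np.linalg.norm(sol.estimate.values))
            resids.append(sol.residual_norm)
        assert all(b <= a * (1 + 1e-12) for a, b in zip(norms, norms[1:]))
        assert all(b >= a * (1 - 1e-12) for a, b in zip(resids, resids[1:]))


class TestTSVD:
    def test_full_rank_is_pseudoinverse(self, rng):
        H = rng.standard_normal((5, 5)) + 3 * np.eye(5)
        y = rng.standard_normal(5)
        T = toy_operator(H)
        sol = tsvd_solve(T, toy_obs(y, T.grid), 5, build_regularizer(0, 5))
        np.testing.assert_allclose(sol.estimate.values,
                                   np.linalg.pinv(H) @ y, rtol=1e-9)

    def test_rank_one_truncation_forced_solution(self):
        H = np.diag([3.0, 1.0])
        grid = GridSpec(dimension=1, length_cm=3.0, density=2 / 3.0)
        T = TransferOperator(impulse=np.zeros(3), matrix=H, grid=grid,
                             constants=None)
        obs = toy_obs([3.0, 1.0], grid)
        from egminv import RegularizerSpec
        sol = tsvd_solve(T, obs, 1, RegularizerSpec(0, np.eye(2)))
        np.testing.assert_allclose(sol.estimate.values, [1.0, 0.0], atol=1e-12)

    def test_modified_tsvd_matches_constrained_optimizer(self, rng):
        """Among rank-k minimizers, modified TSVD minimizes ||R v||."""
        n, k = 5, 3
        H = rng.standard_normal((n, n))
        y = rng.standard_normal(n)
        T = toy_operator(H)
        reg = build_regularizer(1, n)
        sol = tsvd_solve(T, toy_obs(y, T.grid), k, reg)
        U, s, Vt = np.linalg.svd(H)
        x_k = Vt[:k].T @ ((U[:, :k].T @ y) / s[:k])
        V0 = Vt[k:].T

        # brute force: min ||R (x_k + V0 w)|| over w
        def objective(w):
            return np.sum((reg.matrix @ (x_k + V0 @ w)) ** 2)

        res = minimize(objective, np.zeros(n - k), method="BFGS",
                       options={"gtol": 1e-14})
        np.testing.assert_allclose(sol.estimate.values, x_k + V0 @ res.x,
                                   rtol=1e-6, atol=1e-6)

    def test_residual_monotone_in_k(self, model64):
        _, _, T, obs = model64
        reg = build_regularizer(0, T.grid.n_axis)
        resids = [tsvd_solve(T, obs, k, reg).residual_norm
                  for k in (1, 8, 16, 32, 64)]
        assert all(b <= a * (1 + 1e-10) for a, b in zip(resids, resids[1:]))

    def test_out_of_range_k_rejected(self, model64):
        _, _, T, obs = model64
        reg = build_regularizer(0, T.grid.n_axis)
        with pytest.raises(ParameterError):
            tsvd_solve(T, obs, 0, reg)
        with pytest.raises(ParameterError):
            tsvd_solve(T, obs, 10_000, reg)


class TestTotalVariation:
    def test_gamma_zero_is_least_squares(self, rng):
        H = rng.standard_normal((6, 6)) + 3 * np.eye(6)
        y = rng.standard_normal(6)
        T = toy_operator(H)
        sol = tv_solve(T, toy_obs(y, T.grid), 0.0, build_regularizer(1, 6))
        np.testing.assert_allclose(sol.estimate.values,
                                   np.linalg.lstsq(H, y, rcond=None)[0],
                                   rtol=1e-8)

    def test_large_gamma_reduces_seminorm_below_ls(self, rng):
        H = rng.standard_normal((6, 6)) + 3 * np.eye(6)
        y = rng.standard_normal(6) * 5
        T = toy_operator(H)
        reg = build_regularizer(1, 6)
        ls = np.linalg.lstsq(H, y, rcond=None)[0]
        sol = tv_solve(T, toy_obs(y, T.grid), 50.0, reg)
        assert np.sum(np.abs(reg.matrix @ sol.estimate.values)) <= \
            np.sum(np.abs(reg.matrix @ ls)) + 1e-9

    @pytest.mark.parametrize("order", [1, 2])
    def test_matches_generic_convex_solver(self, order, rng):
        """ADMM objective value agrees with a generic minimizer on a toy."""
        n = 5
        H = rng.standard_normal((n, n)) + 2 * np.eye(n)
        y = rng.standard_normal(n) * 2
        gamma = 0.8
        T = toy_operator(H)
        reg = build_regularizer(order, n)
        R = reg.matrix

        def objective(v):
            return 0.5 * np.sum((y - H @ v) ** 2) + gamma * np.sum(np.abs(R @ v))

        sol = tv_solve(T, toy_obs(y, T.grid), gamma, reg)
        # Nelder-Mead refined from the ADMM answer and from zero
        best = np.inf
        for x0 in (np.zeros(n), sol.estimate.values):
            r = minimize(objective, x0, method="Nelder-Mead",
                         options={"xatol": 1e-10, "fatol": 1e-12,
                                  "maxiter": 50_000, "maxfev": 50_000})
            best = min(best, r.fun)
        assert objective(sol.estimate.values) == pytest.approx(best, abs=1e-6)

    def test_requires_derivative_penalty(self, model64):
        _, _, T, obs = model64
        with pytest.raises(ParameterError):
            tv_solve(T, obs, 1.0, build_regularizer(0, T.grid.n_axis))


class TestNoiselessRecovery:
    def test_tuned_inversion_reaches_micro_mae_1d(self):
        """Noiseless 240-node model: full-truncation TSVD recovers the source
        to better than 1e-3 mV mean absolute error."""
        grid = GridSpec(dimension=1)
        from egminv.sources import action_potential_profile_1d
        from egminv.experiments_bench import mae

        src = action_potential_profile_1d(grid)
        T = build_transfer_matrix(grid)
        obs = forward(src, T)
        sol = tsvd_solve(T, obs, grid.n_nodes, build_regularizer(1, grid.n_axis))
        assert mae(sol.estimate, src) <= 1e-3
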