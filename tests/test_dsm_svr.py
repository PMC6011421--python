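"""DSM-SVR: kernel construction, convexity correction, dual solution."""

import numpy as np
import pytest
from scipy.optimize import minimize

from egminv import (
    GridSpec,
    SVRParams,
    build_transfer_matrix,
    dsm_svr_solve,
    forward,
    impulse_response,
    laplacian_distance_kernel,
    nu_svr_fit,
    operator_kernel,
    predict_ve,
    psd_correct,
    reconstruct_vm,
)
from egminv.exceptions import ConfigurationError, GeometryError
from egminv.sources import action_potential_profile_1d, delta_source


def brute_force_nu_svr_dual(K, y, nu, C, tol=1e-12):
    """Independent oracle: solve the free-bias nu-SVR dual with SLSQP.

    Variables are (alpha, alpha*); maximize
        -1/2 (a - a*)^T K (a - a*) + y^T (a - a*)
    subject to 0 <= a, a* <= C/N, sum(a - a*) = 0, sum(a + a*) <= C nu.
    Returns beta = a - a*.
    """
    n = len(y)
    box = C / n

    def neg_obj(x):
        beta = x[:n] - x[n:]
        return 0.5 * beta @ K @ beta - y @ beta

    def neg_obj_grad(x):
        beta = x[:n] - x[n:]
        g = K @ beta - y
        return np.concatenate([g, -g])

    cons = [
        {"type": "eq", "fun": lambda x: np.sum(x[:n] - x[n:]),
         "jac": lambda x: np.concatenate([np.ones(n), -np.ones(n)])},
        {"type": "ineq", "fun": lambda x: C * nu - np.sum(x),
         "jac": lambda x: -np.ones(2 * n)},
    ]
    res = minimize(neg_obj, np.full(2 * n, 0.1 * box), jac=neg_obj_grad,
                   bounds=[(0.0, box)] * (2 * n), constraints=cons,
                   method="SLSQP", options={"maxiter": 2000, "ftol": tol})
    assert res.success, res.message
    return res.x[:n] - res.x[n:]


def brute_force_fixed_b_dual(K, y, nu, C, b, tol=1e-12):
    """Oracle for the fixed-bias dual: no equality constraint."""
    n = len(y)
    box = C / n

    def neg_obj(x):
        beta = x[:n] - x[n:]
        return 0.5 * beta @ K @ beta - (y - b) @ beta

    cons = [{"type": "ineq", "fun": lambda x: C * nu - np.sum(x)}]
    res = minimize(neg_obj, np.full(2 * n, 0.1 * box),
                   bounds=[(0.0, box)] * (2 * n), constraints=cons,
                   method="SLSQP", options={"maxiter": 2000, "ftol": tol})
    assert res.success, res.message
    return res.x[:n] - res.x[n:]


class TestLaplacianDistanceKernel:
    def test_symmetric_for_identical_points(self):
        pts = np.linspace(-1, 1, 9)
        K = laplacian_distance_kernel(pts, pts, 0.02)
        np.testing.assert_array_equal(K, K.T)

    def test_diagonal_is_radial_origin_value_2d(self):
        pts = np.random.default_rng(0).uniform(-1, 1, (6, 2))
        K = laplacian_distance_kernel(pts, pts, 0.02, dimension=2)
        # -2c/z0^3, which also matches the finite-difference Laplacian of
        # Gamma at the origin (see model-core tests)
        np.testing.assert_allclose(np.diag(K), -250000.0, rtol=1e-12)

    def test_entries_equal_impulse_response_at_l1_distance(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-1, 1, (5, 2))
        K = laplacian_distance_kernel(pts, pts, 0.02, dimension=2)
        for i in range(5):
            for j in range(5):
                d = np.abs(pts[i] - pts[j]).sum()
                expected = impulse_response(np.array([d, 0.0]), 0.02,
                                            dimension=2)
                assert K[i, j] == pytest.approx(expected, rel=1e-13)

    def test_matches_operator_kernel_1d_clean(self, grid64):
        T = build_transfer_matrix(grid64)
        pts = grid64.coords()
        K = laplacian_distance_kernel(pts, pts, grid64.z0, T.constants,
                                      dimension=1)
        np.testing.assert_allclose(K, operator_kernel(T), rtol=1e-12)

    def test_invalid_height(self):
        with pytest.raises(GeometryError):
            laplacian_distance_kernel([0.0], [0.0], 0.0)


class TestPsdCorrect:
    def test_psd_input_gets_diagonal_loading_only(self):
        K = np.array([[2.0, 1.0], [1.0, 2.0]])
        out, flipped = psd_correct(K, gamma_dl=0.5)
        assert not flipped
        np.testing.assert_allclose(out, K + 0.5 * np.eye(2), atol=1e-12)

    def test_indefinite_clipping(self):
        K = np.array([[0.0, 1.0], [1.0, 0.0]])  # eigenvalues +-1
        out, flipped = psd_correct(K)
        assert not flipped
        np.testing.assert_allclose(out, [[0.5, 0.5], [0.5, 0.5]], atol=1e-12)

    def test_negative_spectrum_flips_sign(self):
        K = -np.array([[2.0, 0.5], [0.5, 2.0]])
        out, flipped = psd_correct(K)
        assert flipped
        np.testing.assert_allclose(out, -K, atol=1e-12)

    def test_output_is_psd(self, rng):
        A = rng.standard_normal((8, 8))
        K = A + A.T
        out, _ = psd_correct(K)
        assert np.linalg.eigvalsh(out).min() >= -1e-10

    def test_non_symmetric_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            psd_correct(rng.standard_normal((4, 4)))


class TestNuSvrFit:
    def test_constant_target_gives_zero_coefficients(self, rng):
        K = np.eye(6) * 2.0
        y = np.full(6, 3.7)
        sol = nu_svr_fit(K, y, SVRParams(nu=0.5, C=10.0))
        np.testing.assert_allclose(sol.beta, 0.0, atol=1e-6)
        assert sol.b == pytest.approx(3.7, abs=1e-6)

    def test_box_constraint_holds(self, model64):
        grid, src, T, obs = model64
        K, _ = psd_correct(operator_kernel(T))
        params = SVRParams(nu=0.6, C=5.0)
        sol = nu_svr_fit(K, obs.values, params)
        assert np.all(np.abs(sol.beta) <= params.C / len(obs.values) + 1e-8)

    def test_equality_constraint_kkt_mode(self, model64):
        grid, src, T, obs = model64
        K, _ = psd_correct(operator_kernel(T))
        sol = nu_svr_fit(K, obs.values, SVRParams(nu=0.5, C=100.0))
        box = 100.0 / len(obs.values)
        assert abs(np.sum(sol.beta)) <= 1e-6 * box * len(obs.values)

    def test_matches_brute_force_qp_oracle(self, rng):
        """libsvm dual coefficients agree with a generic convex-QP solve."""
        n = 5
        A = rng.standard_normal((n, n))
        K = A @ A.T + 0.5 * np.eye(n)
        y = rng.standard_normal(n) * 2.0
        nu, C = 0.7, 4.0
        sol = nu_svr_fit(K, y, SVRParams(nu=nu, C=C), tol=1e-10)
        beta_oracle = brute_force_nu_svr_dual(K, y, nu, C)
        np.testing.assert_allclose(sol.beta, beta_oracle, atol=1e-5)

    def test_fixed_b_matches_brute_force_qp_oracle(self, rng):
        n = 6
        A = rng.standard_normal((n, n))
        K = A @ A.T + 0.5 * np.eye(n)
        y = rng.standard_normal(n) * 2.0
        nu, C, b = 0.8, 5.0, 0.3
        sol = nu_svr_fit(K, y, SVRParams(nu=nu, C=C, b_mode=b), tol=1e-10)
        beta_oracle = brute_force_fixed_b_dual(K, y, nu, C, b)
        np.testing.assert_allclose(sol.beta, beta_oracle, atol=1e-5)
        assert sol.b == b

    def test_nu_property_bounds(self, rng):
        """Margin-error fraction <= nu <= support-vector fraction."""
        n = 40
        A = rng.standard_normal((n, n))
        K = A @ A.T + np.eye(n)
        y = rng.standard_normal(n) * 3.0
        for nu in (0.2, 0.5, 0.8):
            params = SVRParams(nu=nu, C=50.0)
            sol = nu_svr_fit(K, y, params, tol=1e-10)
            n_sv = np.sum(np.abs(sol.beta) > 1e-9)
            box = params.C / n
            n_err = np.sum(np.isclose(np.abs(sol.beta), box, rtol=1e-6))
            assert n_sv / n >= nu - 0.05
            assert n_err / n <= nu + 0.05


class TestReconstructPredict:
    def test_dual_coefficients_are_the_estimate(self, model64):
        grid, src, T, obs = model64
        K, flipped = psd_correct(operator_kernel(T))
        sol = nu_svr_fit(K, obs.values, SVRParams(nu=0.5, C=100.0))
        sol.sign_flipped = flipped
        inv = reconstruct_vm(sol, grid, rescale_measure=False)
        sign = -1.0 if flipped else 1.0
        np.testing.assert_array_equal(inv.estimate.values, sign * sol.beta)

    def test_prediction_at_training_points(self, model64):
        grid, src, T, obs = model64
        K, _ = psd_correct(operator_kernel(T))
        sol = nu_svr_fit(K, obs.values, SVRParams(nu=0.5, C=100.0))
        np.testing.assert_array_equal(predict_ve(sol, sol.kernel),
                                      sol.kernel @ sol.beta + sol.b)

    def test_zero_coefficients_predict_bias(self, model64):
        grid, src, T, obs = model64
        K, _ = psd_correct(operator_kernel(T))
        sol = nu_svr_fit(K, np.full(grid.n_nodes, 2.0), SVRParams(nu=0.5, C=1.0))
        pred = predict_ve(sol, sol.kernel)
        np.testing.assert_allclose(pred, sol.b, atol=1e-5)

    def test_training_points_within_tube_plus_slack(self, model64):
        grid, src, T, obs = model64
        K, _ = psd_correct(operator_kernel(T))
        sol = nu_svr_fit(K, obs.values, SVRParams(nu=0.5, C=100.0))
        resid = np.abs(obs.values - predict_ve(sol, sol.kernel))
        slack = np.maximum(sol.xi, sol.xi_star)
        assert np.all(resid <= sol.epsilon + slack + 1e-6 * np.abs(obs.values).max())

    def test_delta_source_peak_located(self):
        """At moderate SNR the largest dual coefficient sits on the delta."""
        grid = GridSpec(dimension=1, length_cm=3.0, density=64 / 3.0, z0=0.02)
        src = delta_source(grid, 0.0, amplitude=100.0)
        T = build_transfer_matrix(grid)
        obs = forward(src, T)
        from egminv.noise import add_observation_noise

        noisy = add_observation_noise(obs, 25.0, np.random.default_rng(11))
        inv = dsm_svr_solve(T, noisy, SVRParams(nu=0.5, C=50.0, b_mode=0.0))
        assert np.argmax(np.abs(inv.estimate.values)) == \
            np.argmax(np.abs(src.values))

    def test_noiseless_end_to_end_prediction(self):
        """Fitted model reproduces the clean electrogram to < 5 % on 64 nodes."""
        grid = GridSpec(dimension=1, length_cm=3.0, density=64 / 3.0, z0=0.02)
        src = action_potential_profile_1d(grid)
        T = build_transfer_matrix(grid)
        obs = forward(src, T)
        K, flipped = psd_correct(operator_kernel(T))
        sol = nu_svr_fit(K, obs.values,
                         SVRParams(nu=0.9, C=1000.0, b_mode=0.0))
        pred = predict_ve(sol, sol.kernel)
        rel = np.linalg.norm(pred - obs.values) / np.linalg.norm(obs.values)
        assert rel < 0.05

    def test_noiseless_source_recovery_fixed_bias(self, model64):
        grid, src, T, obs = model64
        inv = dsm_svr_solve(T, obs, SVRParams(nu=0.9, C=1000.0, b_mode=0.0))
        from egminv import mae

        assert mae(inv.estimate, src) < 0.05

    def test_no_matrix_inversion_in_module(self):
        """Structural property: the solver never inverts a matrix."""
        import inspect

        import egminv.dsm_svr as mod

        source = inspect.getsource(mod)
        for banned in ("np.linalg.inv", "np.linalg.solve", "np.linalg.lstsq",
                       "scipy.linalg.inv", "cho_solve", "lu_solve", "pinv"):
            assert banned not in source
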