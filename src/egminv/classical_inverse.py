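"""Classical regularized solvers for the electrogram inverse problem.

All solvers estimate the transmembrane potential v_m from the observed
extracellular potential v_e = H v_m, where H is the (ill-conditioned)
discretized convolution operator:

* Tikhonov, orders 0/1/2 (``zot``/``fot``/``sot``):
  v̂ = argmin ||v_e - H v||² + γ² ||R v||², closed form
  v̂ = (HᵀH + γ²RᵀR)⁻¹ Hᵀ v_e, solved by factorization.
* (Modified) truncated SVD, orders 0/1/2 (``ztsvd``/``ftsvd``/``stsvd``):
  rank-k least squares; for derivative penalties the component of the
  solution in the discarded right-singular subspace is chosen to minimize
  ||R v||.
* Total variation, orders 1/2 (``ftv``/``stv``):
  v̂ = argmin ½||v_e - H v||² + γ ||R v||₁, solved by ADMM with adaptive
  penalty; the ℓ1 norm promotes piecewise-constant (order 1) or
  piecewise-linear (order 2) solutions.

R is the identity (order 0) or a banded finite-difference stencil:
rows (-1, 1) for order 1 and (-1, 2, -1) for order 2; in 2-D the 1-D stencil
is applied along each axis and the two row blocks are stacked (anisotropic
coupling for the TV ℓ1 norm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .exceptions import (
    ConfigurationError,
    ConvergenceError,
    IllConditioningError,
    ParameterError,
)
from .fields import ObservationField, SourceField
from .model_core import TransferOperator

__all__ = [
    "RegularizerSpec",
    "InverseSolution",
    "build_regularizer",
    "tikhonov_solve",
    "tsvd_solve",
    "tv_solve",
]

#: method identifiers used by the CLI, tuners and result tables
TIKHONOV_IDS = {"zot": 0, "fot": 1, "sot": 2}
TSVD_IDS = {"ztsvd": 0, "ftsvd": 1, "stsvd": 2}
TV_IDS = {"ftv": 1, "stv": 2}


@dataclass(frozen=True)
class RegularizerSpec:
    """Penalty operator R acting on v_m."""

    order: int
    matrix: np.ndarray

    @property
    def n(self) -> int:
        return self.matrix.shape[1]


@dataclass
class InverseSolution:
    """Estimated transmembrane potential with method identity and diagnostics."""

    estimate: SourceField
    method: str
    params: dict
    residual_norm: float
    seminorm: float
    diagnostics: dict = field(default_factory=dict)


def _diff_operator(order: int, n: int) -> np.ndarray:
    if order == 0:
        return np.eye(n)
    if order == 1:
        R = np.zeros((n - 1, n))
        idx = np.arange(n - 1)
        R[idx, idx] = -1.0
        R[idx, idx + 1] = 1.0
        return R
    if order == 2:
        R = np.zeros((n - 2, n))
        idx = np.arange(n - 2)
        R[idx, idx] = -1.0
        R[idx, idx + 1] = 2.0
        R[idx, idx + 2] = -1.0
        return R
    raise ConfigurationError(f"regularizer order must be 0, 1 or 2, got {order}")


def build_regularizer(order: int, n: int, dimension: int = 1) -> RegularizerSpec:
    """Finite-difference penalty operator of the given order.

    In 2-D, ``n`` is the nodes per axis; the 1-D stencil is applied along x
    and along y and the resulting row blocks are stacked.
    """
    if n < 3:
        raise ParameterError(f"need at least 3 nodes, got {n}")
    if dimension == 1:
        return RegularizerSpec(order, _diff_operator(order, n))
    if dimension == 2:
        D = _diff_operator(order, n)
        eye = np.eye(n)
        Rx = np.kron(eye, D)   # derivative along x (fast axis)
        Ry = np.kron(D, eye)   # derivative along y (slow axis)
        if order == 0:
            return RegularizerSpec(order, np.eye(n * n))
        return RegularizerSpec(order, np.vstack([Rx, Ry]))
    raise ConfigurationError(f"dimension must be 1 or 2, got {dimension}")


def _regularizer_for(T: TransferOperator, order: int) -> RegularizerSpec:
    return build_regularizer(order, T.grid.n_axis, T.grid.dimension)


def _solution(T, v_hat, method, params, obs) -> InverseSolution:
    residual = float(np.linalg.norm(obs.values - T.matrix @ v_hat))
    return InverseSolution(
        estimate=SourceField(v_hat, T.grid),
        method=method,
        params=params,
        residual_norm=residual,
        seminorm=np.nan,  # filled by callers that know R
    )


def tikhonov_solve(T: TransferOperator, obs: ObservationField, gamma: float,
                   reg: RegularizerSpec) -> InverseSolution:
    """Tikhonov-regularized estimate, v̂ = (HᵀH + γ²RᵀR)⁻¹Hᵀv_e."""
    if gamma < 0:
        raise ParameterError(f"gamma must be >= 0, got {gamma}")
    H = T.matrix
    R = reg.matrix
    A = H.T @ H + gamma**2 * (R.T @ R)
    b = H.T @ obs.values
    try:
        c, low = sla.cho_factor(A, check_finite=False)
        v_hat = sla.cho_solve((c, low), b, check_finite=False)
    except np.linalg.LinAlgError:
        if gamma == 0:
            raise IllConditioningError(
                "H^T H is numerically singular; use gamma > 0") from None
        v_hat = sla.solve(A, b, assume_a="sym", check_finite=False)
    if not np.all(np.isfinite(v_hat)):
        raise IllConditioningError("Tikhonov solve produced non-finite values; "
                                   "increase gamma")
    method = {0: "zot", 1: "fot", 2: "sot"}[reg.order]
    sol = _solution(T, v_hat, method, {"gamma": gamma}, obs)
    sol.seminorm = float(np.linalg.norm(R @ v_hat))
    return sol


def tsvd_solve(T: TransferOperator, obs: ObservationField, k: int,
               reg: RegularizerSpec) -> InverseSolution:
    """(Modified) truncated-SVD estimate with truncation parameter k.

    Order 0 returns the plain rank-k pseudoinverse solution.  Orders 1/2
    return the modified TSVD solution: among all minimizers of the rank-k
    data misfit (the truncated solution plus anything in the discarded
    right-singular subspace V0), the one minimizing ||R v|| is
    ``x_k - V0 (R V0)^+ (R x_k)``.
    """
    U, s, Vt = T.svd()
    rank = int(np.sum(s > s[0] * np.finfo(float).eps * max(T.matrix.shape)))
    if not (1 <= k <= rank):
        raise ParameterError(f"truncation k={k} outside [1, rank={rank}]")
    x_k = Vt[:k].T @ ((U[:, :k].T @ obs.values) / s[:k])
    if reg.order > 0 and k < len(s):
        V0 = Vt[k:].T
        R = reg.matrix
        corr, *_ = np.linalg.lstsq(R @ V0, R @ x_k, rcond=None)
        x_k = x_k - V0 @ corr
    method = {0: "ztsvd", 1: "ftsvd", 2: "stsvd"}[reg.order]
    sol = _solution(T, x_k, method, {"k": int(k)}, obs)
    sol.seminorm = float(np.linalg.norm(reg.matrix @ x_k))
    return sol


def _soft_threshold(x: np.ndarray, t: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def tv_solve(T: TransferOperator, obs: ObservationField, gamma: float,
             reg: RegularizerSpec, *, rho: float | None = None,
             tol: float = 1e-8, max_iter: int = 5000,
             init: tuple | None = None) -> InverseSolution:
    """Total-variation estimate, v̂ = argmin ½||v_e − Hv||² + γ||Rv||₁.

    Solved by ADMM on the splitting z = Rv with adaptive penalty (residual
    balancing).  ``init`` warm-starts the iteration from a previous state
    (``diagnostics["admm_state"]`` of a nearby solve), which makes scans
    along a gamma path much cheaper.  Raises :class:`ConvergenceError`
    carrying the last iterate if the primal/dual residuals do not reach
    ``tol`` within ``max_iter``.
    """
    if gamma < 0:
        raise ParameterError(f"gamma must be >= 0, got {gamma}")
    if reg.order not in (1, 2):
        raise ParameterError("TV requires a derivative penalty (order 1 or 2)")
    H, R = T.matrix, reg.matrix
    y = obs.values
    method = {1: "ftv", 2: "stv"}[reg.order]
    if gamma == 0.0:
        v_hat, *_ = np.linalg.lstsq(H, y, rcond=None)
        sol = _solution(T, v_hat, method, {"gamma": 0.0}, obs)
        sol.seminorm = float(np.sum(np.abs(R @ v_hat)))
        return sol

    HtH = H.T @ H
    Hty = H.T @ y
    RtR = R.T @ R
    rho = float(rho) if rho is not None else max(gamma, 1e-6)

    def factor(rho_):
        return sla.cho_factor(HtH + rho_ * RtR, check_finite=False)

    fac = factor(rho)
    n_pen = R.shape[0]
    if init is not None:
        v, z, u = (np.array(a, dtype=float, copy=True) for a in init)
    else:
        z = np.zeros(n_pen)
        u = np.zeros(n_pen)
        v = np.zeros(R.shape[1])
    # relative primal/dual stopping (Boyd et al.), eps_abs tied to the data scale
    eps_abs = tol * max(1.0, float(np.linalg.norm(y)))
    for it in range(max_iter):
        v = sla.cho_solve(fac, Hty + rho * R.T @ (z - u), check_finite=False)
        Rv = R @ v
        z_old = z
        z = _soft_threshold(Rv + u, gamma / rho)
        u = u + Rv - z
        r_primal = np.linalg.norm(Rv - z)
        r_dual = rho * np.linalg.norm(R.T @ (z - z_old))
        eps_pri = np.sqrt(n_pen) * eps_abs + tol * max(np.linalg.norm(Rv),
                                                       np.linalg.norm(z))
        eps_dua = np.sqrt(R.shape[1]) * eps_abs + tol * rho * np.linalg.norm(R.T @ u)
        if r_primal < eps_pri and r_dual < eps_dua:
            break
        # residual balancing (Boyd et al. defaults mu=10, tau=2)
        if r_primal > 10.0 * r_dual:
            rho *= 2.0
            u /= 2.0
            fac = factor(rho)
        elif r_dual > 10.0 * r_primal:
            rho /= 2.0
            u *= 2.0
            fac = factor(rho)
    else:
        err = ConvergenceError(
            f"TV ADMM did not converge in {max_iter} iterations "
            f"(primal {r_primal:.2e}, dual {r_dual:.2e})",
            last_iterate=v,
        )
        err.state = (v.copy(), z.copy(), u.copy())
        raise err
    sol = _solution(T, v, method, {"gamma": gamma}, obs)
    sol.diagnostics["admm_iterations"] = it + 1
    sol.diagnostics["admm_state"] = (v.copy(), z.copy(), u.copy())
    sol.seminorm = float(np.sum(np.abs(R @ v)))
    return sol
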