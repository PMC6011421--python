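"""Model/Results interface over the inverse solvers.

:class:`InverseProblem` bundles the observed electrogram field, the transfer
operator and (optionally) the ground-truth source; :meth:`InverseProblem.fit`
runs one of the registered solvers — with a fixed parameter or with automatic
tuning — and returns an :class:`InverseProblemResults` carrying the estimate,
its diagnostics and a ``summary()`` table.

>>> T = build_transfer_matrix(GridSpec(dimension=1))
>>> vm = action_potential_profile_1d(T.grid)
>>> prob = InverseProblem(forward(vm, T), T, truth=vm)
>>> res = prob.fit(method="fot", tuner="lcurve")
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError
from .classical_inverse import TIKHONOV_IDS, TSVD_IDS, TV_IDS, InverseSolution
from .dsm_svr import SVRParams, dsm_svr_solve
from .fields import ObservationField, SourceField
from .model_core import TransferOperator
from .tuning import TuningTrace, default_candidates, l_curve, loo_error, \
    loo_error_path, shrinking_grid_search, solve_with

__all__ = ["InverseProblem", "InverseProblemResults", "METHOD_IDS"]

METHOD_IDS = sorted(TIKHONOV_IDS | TSVD_IDS | TV_IDS | {"dsmsvr": None})


@dataclass
class InverseProblemResults:
    """Fit results: estimate, tuned parameters and diagnostics."""

    solution: InverseSolution
    model: "InverseProblem"
    tuner: str | None = None
    trace: TuningTrace | None = None

    @property
    def estimate(self) -> SourceField:
        return self.solution.estimate

    @property
    def method(self) -> str:
        return self.solution.method

    @property
    def params(self) -> dict:
        return self.solution.params

    @property
    def residual_norm(self) -> float:
        return self.solution.residual_norm

    @property
    def seminorm(self) -> float:
        return self.solution.seminorm

    def mae(self, truth: SourceField | None = None) -> float:
        """Mean absolute error against the ground truth (mV)."""
        from .experiments_bench import mae

        truth = truth if truth is not None else self.model.truth
        if truth is None:
            raise ParameterError("no ground-truth source available")
        return mae(self.estimate, truth)

    def summary(self) -> str:
        g = self.model.transfer.grid
        lines = [
            "Intracardiac inverse problem — fit summary",
            "=" * 46,
            f"{'method':<22}{self.method}",
            f"{'tuner':<22}{self.tuner or 'fixed parameter'}",
            f"{'grid':<22}{g.dimension}-D, {g.n_nodes} nodes "
            f"(z0 = {g.z0} cm, spacing = {g.spacing:.4g} cm)",
        ]
        for key, val in self.params.items():
            lines.append(f"{'param ' + key:<22}{val:.6g}" if isinstance(val, float)
                         else f"{'param ' + key:<22}{val}")
        lines.append(f"{'residual norm':<22}{self.residual_norm:.6g}")
        lines.append(f"{'penalty seminorm':<22}{self.seminorm:.6g}")
        if self.model.truth is not None:
            lines.append(f"{'MAE vs truth (mV)':<22}{self.mae():.6g}")
        for key, val in self.solution.diagnostics.items():
            lines.append(f"{key:<22}{val}")
        return "\n".join(lines)


class InverseProblem:
    """Inverse reconstruction of transmembrane potentials from electrograms.

    Parameters
    ----------
    observations : ObservationField
        Measured extracellular potentials on the sensor grid.
    transfer : TransferOperator
        Discretized forward operator (possibly noise-perturbed).
    truth : SourceField, optional
        Ground-truth source for error reporting in simulations.
    """

    def __init__(self, observations: ObservationField, transfer: TransferOperator,
                 truth: SourceField | None = None):
        self.observations = observations
        self.transfer = transfer
        self.truth = truth

    @classmethod
    def from_simulation(cls, source: SourceField, transfer: TransferOperator,
                        noise=None) -> "InverseProblem":
        """Forward-simulate observations from a known source (optionally noisy)."""
        from .model_core import forward
        from .noise import add_observation_noise

        obs = forward(source, transfer)
        if noise is not None:
            snr_db, rng = noise
            obs = add_observation_noise(obs, snr_db, rng)
        return cls(obs, transfer, truth=source)

    def fit(self, method: str = "fot", param=None, tuner: str | None = None,
            svr_params: SVRParams | None = None,
            tuner_options: dict | None = None) -> InverseProblemResults:
        """Run a solver, optionally tuning its free parameter(s) first.

        ``method`` is one of ``zot``/``fot``/``sot`` (Tikhonov),
        ``ztsvd``/``ftsvd``/``stsvd`` (modified TSVD), ``ftv``/``stv``
        (total variation) or ``dsmsvr``.  ``tuner`` is ``lcurve``, ``loo`` or
        ``grid`` (DSM-SVR only); with no tuner, ``param`` (classical) or
        ``svr_params`` (DSM-SVR) must be given.
        """
        opts = dict(tuner_options or {})
        if method == "dsmsvr":
            return self._fit_svr(svr_params, tuner, opts)
        if method not in set(TIKHONOV_IDS) | set(TSVD_IDS) | set(TV_IDS):
            raise ParameterError(
                f"unknown method {method!r}; valid ids: {', '.join(METHOD_IDS)}")
        trace = None
        solver_opts = opts.pop("solver_opts", {})
        if tuner is None:
            if param is None:
                raise ParameterError("either a parameter or a tuner is required")
        elif tuner == "lcurve":
            cands = opts.pop("candidates", None)
            if cands is None:
                cands = default_candidates(self.transfer, method,
                                           num=opts.pop("num_candidates", 15),
                                           obs=self.observations)
            param, trace = l_curve(self.transfer, self.observations, method, cands,
                                   **solver_opts)
        elif tuner == "loo":
            cands = opts.pop("candidates", None)
            if cands is None:
                cands = default_candidates(self.transfer, method,
                                           num=opts.pop("num_candidates", 15),
                                           obs=self.observations)
            folds = opts.pop("folds", None)
            rng = opts.pop("rng", 0)
            strict = opts.pop("strict", True)
            trace = TuningTrace()
            scores = loo_error_path(self.transfer, self.observations, method,
                                    cands, folds=folds, rng=rng,
                                    solver_opts=solver_opts, strict=strict)
            trace.evaluated = list(cands)
            trace.scores = list(scores)
            if not np.any(np.isfinite(scores)):
                raise ParameterError("no candidate produced a converged solve")
            param = trace.evaluated[int(np.argmin(trace.scores))]
            trace.optimum = param
            trace.iterations = 1
            trace.converged = True
        else:
            raise ParameterError(f"unknown tuner {tuner!r} for method {method!r}")
        sol = solve_with(self.transfer, self.observations, method, param,
                         **solver_opts)
        return InverseProblemResults(sol, self, tuner=tuner, trace=trace)

    def _fit_svr(self, svr_params, tuner, opts) -> InverseProblemResults:
        trace = None
        if tuner is None:
            if svr_params is None:
                raise ParameterError("dsmsvr needs svr_params or tuner='grid'/'loo'")
        elif tuner in ("grid", "loo"):
            svr_params, trace = self.tune_svr(**opts)
        else:
            raise ParameterError(f"unknown tuner {tuner!r} for dsmsvr")
        sol = dsm_svr_solve(self.transfer, self.observations, svr_params,
                            rescale_measure=opts.pop("rescale_measure", True))
        return InverseProblemResults(sol, self, tuner=tuner, trace=trace)

    def tune_svr(self, nu_bounds=(0.05, 0.95), c_bounds=None,
                 gamma_bounds=None, folds: int | None = 24, rng=0,
                 shrink: float = 0.5, max_iter: int = 3,
                 tol: float = 1e-3, b_mode: str | float = 0.0
                 ) -> tuple[SVRParams, TuningTrace]:
        """Shrinking-grid search of (nu, gamma_dl, C) minimizing LOO error.

        Default bounds adapt to the problem scale: C spans the range needed
        for the box constraint C/N to cover plausible source amplitudes, and
        the diagonal loading spans many decades of the kernel's own scale.
        The bias is fixed at 0 by default (the synthetic electrograms carry
        no offset, and a fixed bias lets the dual coefficients represent a
        source with nonzero mean); pass ``b_mode='kkt'`` for the free-bias
        dual.
        """
        T, obs = self.transfer, self.observations
        n = obs.values.size
        k_scale = float(np.abs(T.matrix).max()) / T.grid.cell_measure
        if c_bounds is None:
            y_scale = max(float(np.abs(obs.values).max()), 1e-12)
            c_hi = 1e3 * n * y_scale / k_scale
            c_bounds = (c_hi * 1e-6, c_hi)
        if gamma_bounds is None:
            # diagonal loading is a *numerical* safeguard; keeping it well
            # below the kernel's own diagonal prevents the search from
            # degenerating into a self-interpolation model
            gamma_bounds = (k_scale * 1e-9, k_scale * 1e-2)

        def objective(nu, gamma_dl, C):
            params = SVRParams(nu=float(nu), C=float(C), gamma_dl=float(gamma_dl),
                               b_mode=b_mode)
            return loo_error(T, obs, "dsmsvr", params, folds=folds, rng=rng,
                             fit_opts={"tol": 1e-6, "max_iter": 2500,
                                       "strict": False})

        best, trace = shrinking_grid_search(
            bounds=[nu_bounds, gamma_bounds, c_bounds],
            scales=["linear", "log", "log"],
            objective=objective, shrink=shrink, max_iter=max_iter, tol=tol,
        )
        params = SVRParams(nu=float(best[0]), C=float(best[2]),
                           gamma_dl=float(best[1]), b_mode=b_mode)
        return params, trace
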