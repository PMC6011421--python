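"""Free-parameter selection: L-curve corner, leave-one-out, shrinking grid.

* :func:`l_curve` picks a regularization strength at the corner of the
  log-log curve of solution seminorm versus residual norm, located with the
  triangle method on the discrete curve (no spline fitting).
* :func:`loo_error` scores a parameter by observation-space leave-one-out:
  re-solve without sensor i, forward-predict sensor i through its row of H
  (or its kernel row for DSM-SVR), average the absolute errors.  ``folds``
  caps the number of left-out sensors for large problems (a random but
  seeded subset).
* :func:`shrinking_grid_search` is a non-uniform grid descent: 3 points per
  parameter (lo/mid/hi on a linear or log scale), all 3^p combinations
  scored, then the bounds shrink around the best point and the process
  repeats until the intervals collapse or ``max_iter`` is hit.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError
from .classical_inverse import (
    TIKHONOV_IDS,
    TSVD_IDS,
    TV_IDS,
    build_regularizer,
    tikhonov_solve,
    tsvd_solve,
    tv_solve,
)
from .fields import ObservationField
from .model_core import TransferOperator

__all__ = ["TuningTrace", "l_curve", "loo_error", "shrinking_grid_search",
           "solve_with", "default_candidates"]


@dataclass
class TuningTrace:
    """Record of a parameter search."""

    evaluated: list = field(default_factory=list)   # parameter tuples / scalars
    scores: list = field(default_factory=list)      # objective per evaluation
    optimum: object = None
    iterations: int = 0
    converged: bool = False
    evals_per_iter: list = field(default_factory=list)  # combinations scored per pass


def solve_with(T: TransferOperator, obs: ObservationField, method: str, param,
               **solver_opts):
    """Dispatch a classical solve by method id with a scalar parameter.

    ``solver_opts`` (tol, max_iter, rho) are forwarded to the TV solver and
    ignored by the direct solvers.
    """
    n = T.grid.n_axis
    dim = T.grid.dimension
    if method in TIKHONOV_IDS:
        reg = build_regularizer(TIKHONOV_IDS[method], n, dim)
        return tikhonov_solve(T, obs, float(param), reg)
    if method in TSVD_IDS:
        reg = build_regularizer(TSVD_IDS[method], n, dim)
        return tsvd_solve(T, obs, int(param), reg)
    if method in TV_IDS:
        reg = build_regularizer(TV_IDS[method], n, dim)
        return tv_solve(T, obs, float(param), reg, **solver_opts)
    raise ParameterError(f"unknown classical method id {method!r}")


def default_candidates(T: TransferOperator, method: str, num: int = 15,
                       obs: ObservationField | None = None) -> np.ndarray:
    """Reasonable parameter grids per method for tuner scans.

    TSVD gets the full truncation range.  Tikhonov gets a log grid spanning
    the singular-value range of H (gamma enters squared, on the same scale
    as the singular values).  TV gets a log grid up to the LASSO-style
    deactivation scale ||H^T v_e||_inf, above which the l1 penalty fully
    dominates the squared data term.
    """
    if method in TSVD_IDS:
        n = min(T.matrix.shape)
        ks = np.unique(np.linspace(1, n, num=min(num, n), dtype=int))
        return ks
    if method in TV_IDS and obs is not None:
        hi = float(np.abs(T.matrix.T @ obs.values).max())
        return np.geomspace(hi * 1e-8, hi, num=num)
    s = T.svd()[1]
    s_pos = s[s > 0]
    lo = max(s_pos.min(), s_pos.max() * 1e-12)
    return np.geomspace(lo * 1e-2, s_pos.max() * 100, num=num)


def l_curve(T: TransferOperator, obs: ObservationField, solver: str,
            candidates, **solver_opts) -> tuple[float, TuningTrace]:
    """Corner of the discrete L-curve over the candidate parameters.

    Returns the candidate at the point of maximum curvature, found as the
    vertex with the sharpest angle to the curve endpoints (triangle method).
    Falls back to the median candidate with a warning if the curve is
    degenerate (collinear); candidates whose solve does not converge are
    dropped from the curve.
    """
    candidates = np.asarray(candidates)
    if candidates.size < 5:
        raise ParameterError("need at least 5 candidate parameters")
    trace = TuningTrace()
    pts = []
    kept = []
    warm = None  # ADMM path continuation along ascending gamma (TV only)
    for cand in candidates:
        opts = dict(solver_opts)
        if solver in TV_IDS and warm is not None:
            opts.setdefault("init", warm)
        try:
            sol = solve_with(T, obs, solver, cand, **opts)
            if solver in TV_IDS:
                warm = sol.diagnostics.get("admm_state")
        except Exception as exc:
            warm = getattr(exc, "state", warm)
            continue
        resid = max(sol.residual_norm, 1e-300)
        semi = max(sol.seminorm, 1e-300)
        pts.append((np.log10(resid), np.log10(semi)))
        kept.append(cand)
        trace.evaluated.append(cand)
        trace.scores.append(np.nan)
    if len(kept) < 3:
        raise ParameterError("too few candidates produced a converged solve")
    candidates = np.asarray(kept)
    P = np.asarray(pts)
    # normalize both log-axes to the unit box so the corner geometry is not
    # dominated by whichever quantity spans more decades
    span_xy = P.max(axis=0) - P.min(axis=0)
    span_xy[span_xy < 1e-12] = 1.0
    P = (P - P.min(axis=0)) / span_xy

    # terminal cliff: when the last segment carries most of the residual
    # range at nearly constant seminorm (typical of truncated-SVD curves
    # where only full truncation fits the data), the discrete corner is the
    # final candidate itself
    if (P[-2, 0] - P[-1, 0]) > 0.5 and abs(P[-1, 1] - P[-2, 1]) < 0.2:
        trace.optimum = candidates[-1]
        trace.iterations = 1
        trace.converged = True
        trace.scores = [np.nan] * len(candidates)
        return candidates[-1], trace

    first, last = P[0], P[-1]
    span = np.linalg.norm(last - first)
    best_idx, best_angle = None, np.pi
    for j in range(1, len(P) - 1):
        a = first - P[j]
        b = last - P[j]
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na < 1e-12 * (1 + span) or nb < 1e-12 * (1 + span):
            continue
        cross = a[0] * b[1] - a[1] * b[0]
        # corner must be on the convex side of the chord (below it for an
        # L-shaped residual/seminorm trade-off)
        if cross <= 0:
            continue
        angle = np.arccos(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))
        if angle < best_angle:
            best_angle, best_idx = angle, j
    if best_idx is None or best_angle > np.pi - 1e-3:
        warnings.warn("degenerate (collinear) L-curve; falling back to the "
                      "median candidate", stacklevel=2)
        best_idx = len(candidates) // 2
    best = candidates[best_idx]
    trace.optimum = best
    trace.iterations = 1
    trace.converged = True
    trace.scores = [float(best_angle) if i == best_idx else np.nan
                    for i in range(len(candidates))]
    return best, trace


def _sample_folds(values: np.ndarray, folds: int | None, rng,
                  weighted: bool = False) -> np.ndarray:
    """Held-out sensor subset for subsampled leave-one-out.

    With ``weighted`` the sensors are drawn with probability proportional
    to |v_e| so the validation set covers the informative region.  This is
    required for the DSM-SVR score: on a field with a small active area,
    uniformly sampled folds mostly score quiet sensors, which the
    degenerate all-zero model predicts perfectly.  Classical solvers keep
    uniform sampling.
    """
    n = len(values)
    if folds is None or folds >= n:
        return np.arange(n)
    rng = np.random.default_rng(rng)
    p = None
    if weighted:
        w = np.abs(values)
        if w.sum() > 0:
            p = w / w.sum()
    return np.sort(rng.choice(n, size=folds, replace=False, p=p))


def _classical_loo(T, obs, solver, param, folds_idx, solver_opts=None) -> float:
    H = T.matrix
    y = obs.values
    errors = []
    for i in folds_idx:
        keep = np.ones(len(y), dtype=bool)
        keep[i] = False
        T_i = TransferOperator(impulse=T.impulse, matrix=H[keep], grid=T.grid,
                               constants=T.constants)
        obs_i = ObservationField.__new__(ObservationField)
        obs_i.values = y[keep]
        obs_i.grid = T.grid
        p_i = param
        if solver in TSVD_IDS:
            # a fold has one observation fewer; clamp the truncation
            p_i = min(int(param), min(T_i.matrix.shape))
        sol = solve_with(T_i, obs_i, solver, p_i, **(solver_opts or {}))
        pred = H[i] @ sol.estimate.values
        errors.append(abs(pred - y[i]))
    return float(np.mean(errors))


def _grid_neighbors(i: int, n_axis: int, dimension: int) -> list[int]:
    """Indices of the in-grid spatial neighbors of flat node i."""
    if dimension == 1:
        return [j for j in (i - 1, i + 1) if 0 <= j < n_axis]
    iy, ix = divmod(i, n_axis)
    out = []
    for dy, dx in ((0, -1), (0, 1), (-1, 0), (1, 0)):
        jy, jx = iy + dy, ix + dx
        if 0 <= jy < n_axis and 0 <= jx < n_axis:
            out.append(jy * n_axis + jx)
    return out


def _svr_loo(T, obs, params, folds_idx, fit_opts=None) -> float:
    from .dsm_svr import _spectral_norm, nu_svr_fit, operator_kernel, psd_correct

    K_raw = operator_kernel(T)
    K, _ = psd_correct(K_raw, params.gamma_dl)
    # Lipschitz bound shared across folds (a principal submatrix of a PSD
    # matrix has a smaller spectral norm)
    lip = _spectral_norm(K) * 1.05
    y = obs.values
    errors = []
    for i in folds_idx:
        keep = np.ones(len(y), dtype=bool)
        keep[i] = False
        sol = nu_svr_fit(K[np.ix_(keep, keep)], y[keep], params, lipschitz=lip,
                         **(fit_opts or {}))
        # Dropping sensor i also drops the co-located source coefficient,
        # whose self-term h(0)*beta_i dominates the held-out electrogram.
        # Interpolate that coefficient from its spatial neighbors so the
        # prediction is comparable with the classical leave-one-out (which
        # keeps the source grid intact).
        beta_full = np.zeros(len(y))
        beta_full[keep] = sol.beta
        nbrs = [j for j in _grid_neighbors(i, T.grid.n_axis, T.grid.dimension)
                if keep[j]]
        if nbrs:
            beta_full[i] = float(np.mean(beta_full[nbrs]))
        pred = K[i] @ beta_full + sol.b
        errors.append(abs(pred - y[i]))
    return float(np.mean(errors))


def loo_error(T: TransferOperator, obs: ObservationField, solver: str, parameter,
              folds: int | None = None, rng=None,
              solver_opts: dict | None = None,
              fit_opts: dict | None = None) -> float:
    """Observation-space leave-one-out mean absolute validation error.

    For each left-out sensor the model is refitted on the remaining sensors
    and the held-out observation is predicted through the forward operator
    (classical solvers) or the kernel row (``dsmsvr``).  ``folds`` caps the
    number of sensors left out (seeded random subset; default: all).
    """
    n = obs.values.size
    if n < 3:
        raise ParameterError("leave-one-out needs at least 3 observations")
    folds_idx = _sample_folds(obs.values, folds, rng,
                              weighted=(solver == "dsmsvr"))
    if solver == "dsmsvr":
        return _svr_loo(T, obs, parameter, folds_idx, fit_opts=fit_opts)
    return _classical_loo(T, obs, solver, parameter, folds_idx, solver_opts)


def loo_error_path(T: TransferOperator, obs: ObservationField, solver: str,
                   candidates, folds: int | None = None, rng=None,
                   solver_opts: dict | None = None,
                   strict: bool = True) -> np.ndarray:
    """Leave-one-out errors for a whole candidate path at once.

    Equivalent to calling :func:`loo_error` per candidate, but loops folds
    on the outside so per-fold work is shared: the reduced operator's SVD is
    computed once per fold (TSVD scans all truncations on it) and TV solves
    are warm-started along the ascending-gamma path.  With ``strict=False``
    a TV solve that exhausts its iteration budget contributes its last
    iterate instead of failing the candidate.
    """
    candidates = np.asarray(candidates)
    n = obs.values.size
    if n < 3:
        raise ParameterError("leave-one-out needs at least 3 observations")
    folds_idx = _sample_folds(obs.values, folds, rng)
    H = T.matrix
    y = obs.values
    is_tv = solver in TV_IDS
    errs = np.full((candidates.size, folds_idx.size), np.inf)
    for j, i in enumerate(folds_idx):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        T_i = TransferOperator(impulse=T.impulse, matrix=H[keep], grid=T.grid,
                               constants=T.constants)
        obs_i = ObservationField.__new__(ObservationField)
        obs_i.values = y[keep]
        obs_i.grid = T.grid
        warm = None
        for ci, cand in enumerate(candidates):
            opts = dict(solver_opts or {})
            if is_tv and warm is not None:
                opts.setdefault("init", warm)
            if solver in TSVD_IDS:
                # a fold has one observation fewer; clamp the truncation
                cand = min(int(cand), min(T_i.matrix.shape))
            v = None
            try:
                sol = solve_with(T_i, obs_i, solver, cand, **opts)
                v = sol.estimate.values
                if is_tv:
                    warm = sol.diagnostics.get("admm_state")
            except Exception as exc:
                warm = getattr(exc, "state", warm)
                if not strict and getattr(exc, "last_iterate", None) is not None:
                    v = exc.last_iterate
            if v is not None:
                errs[ci, j] = abs(H[i] @ v - y[i])
    return errs.mean(axis=1)


def shrinking_grid_search(bounds, scales, objective, shrink: float = 0.5,
                          max_iter: int = 10, tol: float = 1e-3
                          ) -> tuple[tuple, TuningTrace]:
    """Non-uniform (shrinking) grid descent over p parameters.

    Per iteration the three points lo/mid/hi of each parameter (midpoint on
    its declared linear or log scale) form a 3^p grid; every combination is
    scored, the bounds re-center and shrink around the best point, and the
    loop repeats until every interval is narrower than ``tol`` times its
    initial width or ``max_iter`` is reached.  Objective failures score +inf
    and the search continues.
    """
    bounds = [tuple(map(float, b)) for b in bounds]
    if any(not (np.isfinite(lo) and np.isfinite(hi) and lo < hi) for lo, hi in bounds):
        raise ParameterError("bounds must be finite with lo < hi")
    if len(scales) != len(bounds):
        raise ParameterError("one scale per parameter required")
    for s in scales:
        if s not in ("linear", "log"):
            raise ParameterError(f"scale must be 'linear' or 'log', got {s!r}")
    init_widths = [hi - lo for lo, hi in bounds]
    lo0 = [b[0] for b in bounds]
    hi0 = [b[1] for b in bounds]

    def mid(lo, hi, scale):
        if scale == "log":
            return float(np.sqrt(lo * hi))
        return 0.5 * (lo + hi)

    trace = TuningTrace()
    cur = list(bounds)
    best_point, best_score = None, np.inf
    cache: dict[tuple, float] = {}
    for it in range(max_iter):
        axes = [(lo, mid(lo, hi, sc), hi) for (lo, hi), sc in zip(cur, scales)]
        n_combos = 0
        for combo in itertools.product(*axes):
            n_combos += 1
            if combo in cache:
                score = cache[combo]
            else:
                try:
                    score = float(objective(*combo))
                except Exception:
                    score = np.inf
                cache[combo] = score
                trace.evaluated.append(combo)
                trace.scores.append(score)
            if score < best_score:
                best_score, best_point = score, combo
        trace.iterations = it + 1
        trace.evals_per_iter.append(n_combos)
        new = []
        for dim_i, ((lo, hi), sc) in enumerate(zip(cur, scales)):
            center = best_point[dim_i]
            if sc == "log":
                half = (hi / lo) ** (shrink / 2.0)
                nlo, nhi = center / half, center * half
            else:
                half = shrink * (hi - lo) / 2.0
                nlo, nhi = center - half, center + half
            nlo = max(nlo, lo0[dim_i])
            nhi = min(nhi, hi0[dim_i])
            if nlo >= nhi:  # collapsed onto a bound; keep a sliver inside
                nlo, nhi = center, center
            new.append((nlo, nhi))
        cur = new
        widths_ok = all(
            (hi - lo) < tol * w0 for (lo, hi), w0 in zip(cur, init_widths)
        )
        if widths_ok:
            trace.converged = True
            break
    trace.optimum = best_point
    return best_point, trace
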