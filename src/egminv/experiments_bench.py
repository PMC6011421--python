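"""Benchmark drivers: height sweep, ill-conditioning demo, noise robustness.

All experiments are fully synthetic and seeded; results come back as
long-format :class:`pandas.DataFrame` records (one row per experiment cell)
so they can be written straight to CSV.

The error metric throughout is the mean absolute error (MAE, mV) between the
estimated and the true transmembrane potential over the source nodes.
"""

from __future__ import annotations

import time

import numpy as np
import pandas as pd

from .exceptions import DimensionMismatchError
from .fields import SourceField
from .grid import GridSpec
from .inverse_model import InverseProblem
from .model_core import build_transfer_matrix, forward
from .noise import add_observation_noise, add_transfer_noise
from .sources import action_potential_profile_1d, action_potential_profile_2d, \
    delta_source

__all__ = [
    "mae",
    "height_sweep",
    "ill_conditioning_demo",
    "noise_robustness_sweep",
    "reference_model_1d",
    "reference_model_2d",
    "classical_low_hnr_benchmark",
    "matched_noise_benchmark",
    "dsm_hnr_benchmark",
    "two_d_hnr_benchmark",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = [
    "experiment", "method", "tuner", "noise_target", "level_db", "rep", "seed",
    "mae_mv", "params", "runtime_s",
]


def mae(estimate: SourceField, truth: SourceField) -> float:
    """Mean absolute error between two source fields, in mV."""
    if estimate.grid != truth.grid:
        raise DimensionMismatchError("estimate and truth live on different grids")
    return float(np.mean(np.abs(estimate.values - truth.values)))


def reference_model_1d(z0: float = 0.02, decimation: int = 1,
                       **source_kwargs):
    """The 1-D reference setup: 3 cm line at 80 elements/cm with the
    action-potential source.  Returns (grid, source, transfer, observations)."""
    grid = GridSpec(dimension=1, length_cm=3.0, density=80.0, z0=z0,
                    decimation=decimation)
    src = action_potential_profile_1d(grid, **source_kwargs)
    T = build_transfer_matrix(grid)
    return grid, src, T, forward(src, T)


def reference_model_2d(z0: float = 0.02, decimation: int = 2, mode: str = "radial",
                       **source_kwargs):
    """The 2-D reference setup: 3 cm x 3 cm patch at 80 elements/cm, centered
    action-potential source; decimation keeps the operator tractable."""
    grid = GridSpec(dimension=2, length_cm=3.0, density=80.0, z0=z0,
                    decimation=decimation)
    src = action_potential_profile_2d(grid, mode=mode, **source_kwargs)
    T = build_transfer_matrix(grid)
    return grid, src, T, forward(src, T)


# ---------------------------------------------------------------- height sweep

def _egm_metrics(x: np.ndarray, v: np.ndarray) -> dict:
    """Morphology metrics of a spatial electrogram waveform."""
    peak = float(np.abs(v).max())
    pos = float(v.max())
    neg = float(-v.min())
    above = np.abs(v) > 0.10 * peak
    width = float(x[above].max() - x[above].min()) if above.any() else 0.0
    return {
        "peak_to_peak": pos + neg,
        "width_cm": width,
        "biphasic_ratio": pos / neg if neg > 0 else np.inf,
    }


def height_sweep(z0_values=None, grid_template: GridSpec | None = None,
                 source_kwargs: dict | None = None) -> pd.DataFrame:
    """Forward-simulated electrogram morphology as a function of sensor height.

    For each z0 the 1-D electrogram is computed and normalized to its maximum
    absolute amplitude; the returned frame carries the waveform and its
    morphology metrics (peak-to-peak, 10 %-width, positive/negative lobe
    ratio).  Very small heights approach an inverted delta (ratio → 0), large
    heights a smooth far-field waveform.
    """
    if z0_values is None:
        z0_values = np.geomspace(0.001, 0.4, 9)
    grid_template = grid_template or GridSpec(dimension=1)
    source_kwargs = source_kwargs or {}
    rows = []
    for z0 in np.asarray(z0_values, dtype=float):
        grid = grid_template.with_(z0=z0)
        src = action_potential_profile_1d(grid, **source_kwargs)
        ve = forward(src, build_transfer_matrix(grid)).values
        x = grid.coords()
        norm = ve / np.abs(ve).max()
        rows.append({"z0": z0, "x_cm": x, "egm_norm": norm,
                     **_egm_metrics(x, ve)})
    return pd.DataFrame(rows)


# ------------------------------------------------------- ill-conditioning demo

def ill_conditioning_demo(grid: GridSpec | None = None,
                          snr_values=(15.0, 25.0, 35.0),
                          methods=("fot", "ftsvd", "ftv", "dsmsvr"),
                          position: float = 0.0, seed: int = 0,
                          tuner_options: dict | None = None) -> pd.DataFrame:
    """Estimate a point (delta) source at several SNRs.

    Illustrates the ill-conditioning of the operator: each method's spatial
    estimate of the delta and its discrete-Fourier magnitude (length equal to
    the node count, full two-sided convention) reveal baseline leakage and
    low-frequency distortion that grow as the SNR drops.
    """
    grid = grid or GridSpec(dimension=1, density=80.0 / 3.75)  # 64-node default
    src = delta_source(grid, position, amplitude=100.0)
    T = build_transfer_matrix(grid)
    clean = forward(src, T)
    rows = []
    for i_snr, snr in enumerate(snr_values):
        rng = np.random.default_rng(seed + 1000 * i_snr)
        obs = clean if np.isinf(snr) else add_observation_noise(clean, snr, rng)
        prob = InverseProblem(obs, T, truth=src)
        for method in methods:
            if method == "dsmsvr":
                res = prob.fit(method="dsmsvr", tuner="grid",
                               tuner_options=tuner_options or {"max_iter": 2})
            else:
                res = prob.fit(method=method, tuner="lcurve")
            est = res.estimate.values
            rows.append({
                "method": method, "snr_db": snr, "seed": seed,
                "estimate": est, "spectrum": np.abs(np.fft.fft(est)),
                "mae_mv": res.mae(), "params": res.params,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------- noise robustness sweeps

def noise_robustness_sweep(dimension: int = 1, noise_target: str = "snr",
                           levels_db=(0, 10, 20, 30, 40, 50, 60, 70),
                           methods=("fot", "ftsvd", "ftv"),
                           tuners=("lcurve",), reps: int = 20, seed: int = 0,
                           decimation: int | None = None,
                           svr_params_by_level: dict | None = None,
                           tuner_options: dict | None = None) -> pd.DataFrame:
    """Full-factorial MAE benchmark over methods x tuners x noise levels x reps.

    Noise is injected either into the observations (``snr``) or into the
    transfer operator (``hnr``, symmetry-preserving generator mode).  Each
    cell's MAE is recorded per repetition; infinite level means noiseless
    (identical across reps for a fixed seed).

    For ``dsmsvr``, parameters may be supplied per level through
    ``svr_params_by_level`` (tuned once and reused across repetitions —
    the package's averaging protocol); otherwise they are grid-tuned on the
    first repetition of each level and reused.
    """
    if dimension == 1:
        grid, src, T, clean = reference_model_1d(
            decimation=decimation or 1)
    else:
        grid, src, T, clean = reference_model_2d(
            decimation=decimation or 2)
    rows = []
    svr_cache = dict(svr_params_by_level or {})
    for method in methods:
        for tuner in tuners:
            for level in levels_db:
                level = float(level)
                for rep in range(reps):
                    cell_seed = (seed * 100003 + rep * 1009
                                 + int(level if np.isfinite(level) else 999)) % (2**31)
                    rng = np.random.default_rng(cell_seed)
                    t0 = time.perf_counter()
                    if noise_target == "snr":
                        T_run = T
                        obs = add_observation_noise(clean, level, rng)
                    elif noise_target == "hnr":
                        T_run = add_transfer_noise(T, level, rng)
                        obs = clean
                    else:
                        raise ValueError(f"noise_target must be 'snr' or 'hnr', "
                                         f"got {noise_target!r}")
                    prob = InverseProblem(obs, T_run, truth=src)
                    try:
                        if method == "dsmsvr":
                            if level not in svr_cache:
                                svr_cache[level], _ = prob.tune_svr(
                                    **(tuner_options or {}))
                            res = prob.fit(method="dsmsvr",
                                           svr_params=svr_cache[level])
                        else:
                            res = prob.fit(method=method, tuner=tuner,
                                           tuner_options=tuner_options)
                        err = res.mae()
                        params = res.params
                    except Exception as exc:  # record failures, keep sweeping
                        err, params = np.nan, {"error": str(exc)}
                    rows.append({
                        "experiment": f"{dimension}d_{noise_target}",
                        "method": method, "tuner": tuner,
                        "noise_target": noise_target, "level_db": level,
                        "rep": rep, "seed": cell_seed, "mae_mv": err,
                        "params": params,
                        "runtime_s": time.perf_counter() - t0,
                    })
                    if np.isinf(level):
                        # noiseless cells are deterministic; one rep suffices,
                        # replicate the record for the factorial contract
                        for extra in range(rep + 1, reps):
                            dup = dict(rows[-1])
                            dup["rep"] = extra
                            rows.append(dup)
                        break
    return pd.DataFrame(rows)[RESULT_COLUMNS]


# ------------------------------------------------------ benchmark protocols
#
# The canonical measurement protocols for the headline comparisons.  Noise
# realizations are seeded from a base seed; classical methods are re-tuned
# per realization by subsampled leave-one-out (the package's standard
# protocol), while per-cell protocols tune once on a dedicated realization
# and reuse the parameters across repetitions (documented in the methods
# note).

FTV_TUNER_OPTS = {"strict": False, "num_candidates": 10,
                  "solver_opts": {"tol": 1e-5, "max_iter": 3000}}


def _cell_rng(base_seed: int, rep: int) -> np.random.Generator:
    return np.random.default_rng((base_seed * 100003 + rep * 1009) % (2**31))


def classical_low_hnr_benchmark(level_db: float = 0.0, seeds: int = 20,
                                folds: int = 8, base_seed: int = 0,
                                methods=("fot", "ftsvd", "ftv"),
                                decimation: int = 1) -> dict:
    """Per-method MAE of LOO-tuned classical solvers under transfer noise.

    The reference 1-D model with the action-potential source; each noise
    realization gets its own tuning pass.  Returns arrays of per-seed MAE
    keyed by method id.
    """
    _, src, T, obs = reference_model_1d(decimation=decimation)
    out = {m: [] for m in methods}
    for rep in range(seeds):
        Tn = add_transfer_noise(T, level_db, _cell_rng(base_seed, rep))
        prob = InverseProblem(obs, Tn, truth=src)
        for m in methods:
            opts = {"folds": folds, "rng": rep}
            if m in ("ftv", "stv"):
                opts.update(FTV_TUNER_OPTS)
            out[m].append(prob.fit(method=m, tuner="loo",
                                   tuner_options=opts).mae())
    return {m: np.asarray(v) for m, v in out.items()}


def matched_noise_benchmark(levels_db, targets=("snr", "hnr"), seeds: int = 20,
                            methods=("fot", "ftsvd", "ftv"), folds: int = 8,
                            base_seed: int = 0, decimation: int = 1) -> dict:
    """MAE per (target, level, method) cell, averaged over realizations.

    Parameters are tuned once per cell on a dedicated noise realization and
    reused across the repetitions, keeping matched-dB comparisons between
    observation (SNR) and transfer (HNR) noise affordable.  Tuning follows
    the package's standard assignment: leave-one-out throughout, except that
    truncated-SVD methods under observation noise use the L-curve (their
    leave-one-out score cannot see the full-truncation optimum; see the
    methods note).  Returns ``{(target, level, method): per-seed MAE}``.
    """
    _, src, T, clean = reference_model_1d(decimation=decimation)
    results = {}
    for target in targets:
        for level in levels_db:
            # tuning realization kept distinct from the scored ones
            rng_t = _cell_rng(base_seed + 7919, 0)
            if target == "hnr":
                T_t, obs_t = add_transfer_noise(T, level, rng_t), clean
            else:
                T_t, obs_t = T, add_observation_noise(clean, level, rng_t)
            tuned = {}
            prob_t = InverseProblem(obs_t, T_t, truth=src)
            for m in methods:
                if target == "snr" and m in ("ztsvd", "ftsvd", "stsvd"):
                    res = prob_t.fit(method=m, tuner="lcurve")
                else:
                    opts = {"folds": folds, "rng": 0}
                    if m in ("ftv", "stv"):
                        opts.update(FTV_TUNER_OPTS)
                    res = prob_t.fit(method=m, tuner="loo", tuner_options=opts)
                tuned[m] = next(iter(res.params.values()))
            for m in methods:
                maes = []
                for rep in range(seeds):
                    rng = _cell_rng(base_seed, rep)
                    if target == "hnr":
                        T_r, obs_r = add_transfer_noise(T, level, rng), clean
                    else:
                        T_r, obs_r = T, add_observation_noise(clean, level, rng)
                    prob = InverseProblem(obs_r, T_r, truth=src)
                    solver_opts = (FTV_TUNER_OPTS["solver_opts"]
                                   if m in ("ftv", "stv") else {})
                    try:
                        res = prob.fit(method=m, param=tuned[m],
                                       tuner_options={"solver_opts": solver_opts})
                        maes.append(res.mae())
                    except Exception:
                        maes.append(np.nan)
                results[(target, float(level), m)] = np.asarray(maes)
    return results


def dsm_hnr_benchmark(levels_db, seeds: int = 20, folds: int = 10,
                      base_seed: int = 0, decimation: int = 1,
                      tune_max_iter: int = 2) -> dict:
    """DSM-SVR MAE per HNR level: grid-tuned once per level, scored per seed."""
    _, src, T, clean = reference_model_1d(decimation=decimation)
    results = {}
    for level in levels_db:
        rng_t = _cell_rng(base_seed + 7919, 0)
        T_t = add_transfer_noise(T, level, rng_t)
        prob_t = InverseProblem(clean, T_t, truth=src)
        params, _ = prob_t.tune_svr(folds=folds, max_iter=tune_max_iter,
                                    rng=base_seed)
        maes = []
        for rep in range(seeds):
            T_r = add_transfer_noise(T, level, _cell_rng(base_seed, rep))
            prob = InverseProblem(clean, T_r, truth=src)
            maes.append(prob.fit(method="dsmsvr", svr_params=params).mae())
        results[float(level)] = {"mae": np.asarray(maes), "params": params}
    return results


def two_d_hnr_benchmark(level_db: float = 40.0, decimation: int = 8,
                        seeds: int = 3, base_seed: int = 0,
                        svr_folds: int = 8, svr_max_iter: int = 3) -> dict:
    """2-D patch benchmark: FTV (L-curve) vs DSM-SVR (grid search) MAE.

    Runs at a stated decimation of the 240 x 240 base grid; FTV is re-tuned
    per realization by the L-curve, DSM-SVR is grid-tuned once.
    """
    _, src, T, clean = reference_model_2d(decimation=decimation)
    rng_t = _cell_rng(base_seed + 7919, 0)
    prob_t = InverseProblem(clean, add_transfer_noise(T, level_db, rng_t),
                            truth=src)
    params, _ = prob_t.tune_svr(folds=svr_folds, max_iter=svr_max_iter,
                                rng=base_seed)
    ftv, dsm = [], []
    for rep in range(seeds):
        Tn = add_transfer_noise(T, level_db, _cell_rng(base_seed, rep))
        prob = InverseProblem(clean, Tn, truth=src)
        res = prob.fit(method="ftv", tuner="lcurve",
                       tuner_options={"solver_opts": {"tol": 1e-6,
                                                      "max_iter": 3000}})
        ftv.append(res.mae())
        dsm.append(prob.fit(method="dsmsvr", svr_params=params).mae())
    return {"ftv": np.asarray(ftv), "dsmsvr": np.asarray(dsm),
            "svr_params": params}
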