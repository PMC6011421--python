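"""Plot helpers for the benchmark outputs (matplotlib, optional use)."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["plot_height_sweep", "plot_noise_sweep", "plot_estimate"]


def plot_height_sweep(sweep: pd.DataFrame, ax=None):
    """Overlay normalized electrogram waveforms for each catchment height."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for _, row in sweep.iterrows():
        ax.plot(row["x_cm"], row["egm_norm"], label=f"z0 = {row['z0']:.3g} cm")
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("normalized electrogram")
    ax.legend(fontsize=7)
    return ax


def plot_noise_sweep(results: pd.DataFrame, ax=None):
    """Mean MAE versus noise level per method (semilog-y)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    cells = (results.dropna(subset=["mae_mv"])
             .groupby(["method", "level_db"])["mae_mv"].mean().reset_index())
    for method, grp in cells.groupby("method"):
        grp = grp.sort_values("level_db")
        finite = grp[np.isfinite(grp["level_db"])]
        ax.semilogy(finite["level_db"], finite["mae_mv"], "o-", label=method)
    target = results["noise_target"].iloc[0].upper()
    ax.set_xlabel(f"{target} (dB)")
    ax.set_ylabel("MAE (mV)")
    ax.legend()
    return ax


def plot_estimate(x, truth, estimate, ax=None, label="estimate"):
    """True and estimated transmembrane potentials on a 1-D line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(x, truth, "k-", lw=1.5, label="true $v_m$")
    ax.plot(x, estimate, "r--", lw=1.2, label=label)
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("$v_m$ (mV)")
    ax.legend()
    return ax
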