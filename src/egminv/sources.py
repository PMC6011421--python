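"""Synthetic transmembrane-potential sources.

The benchmark source is a spatial snapshot of a propagating action potential:
a depolarized region (plateau near ``baseline + amplitude``) bounded by a
steep depolarization wavefront on one side and a gradual repolarization edge
on the other, returning to ``baseline`` at the tissue edges.  The template is
a product of two smooth sigmoidal edges; the Gaussian CDF is used as the
sigmoid so the plateau saturates quickly relative to the edge widths while
the profile stays C-infinity smooth.  Only the spatial snapshot at one
instant is modelled — there is no temporal propagation.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import ndtr

from .exceptions import ConfigurationError, DomainError
from .fields import SourceField
from .grid import GridSpec

__all__ = [
    "action_potential_profile_1d",
    "action_potential_profile_2d",
    "delta_source",
]

#: Defaults for the action-potential template (mV / cm).  The depolarization
#: wavefront sits near -0.5 cm and the repolarization edge *ends* (returns to
#: baseline) near +0.5 cm, so the active region is centered on the origin and
#: well inside a 3-cm tissue.
DEFAULT_BASELINE = 0.0
DEFAULT_AMPLITUDE = 100.0
DEFAULT_UPSTROKE_CENTER = -0.5
DEFAULT_UPSTROKE_WIDTH = 0.02
DEFAULT_REPOL_CENTER = 0.2
DEFAULT_REPOL_WIDTH = 0.1


def _template(x: np.ndarray, baseline: float, amplitude: float,
              upstroke_center: float, upstroke_width: float,
              repol_center: float, repol_width: float) -> np.ndarray:
    """Sigmoid-product pulse evaluated at coordinates x."""
    up = ndtr((x - upstroke_center) / upstroke_width)
    down = ndtr((repol_center - x) / repol_width)
    return baseline + amplitude * up * down


def _check_support(grid: GridSpec, upstroke_center: float, upstroke_width: float,
                   repol_center: float, repol_width: float) -> None:
    if not (upstroke_center < repol_center):
        raise ConfigurationError("upstroke_center must lie left of repol_center")
    if upstroke_width <= 0 or repol_width <= 0:
        raise ConfigurationError("edge widths must be positive")
    half = grid.length_cm / 2.0
    # 4 widths ~ where the Gaussian-CDF edge has decayed below 3e-5
    lo = upstroke_center - 4.0 * upstroke_width
    hi = repol_center + 4.0 * repol_width
    if lo < -half or hi > half:
        warnings.warn(
            "active region extends to the tissue boundary; the simulated "
            "electrogram will include boundary contamination",
            stacklevel=3,
        )


def action_potential_profile_1d(
    grid: GridSpec,
    baseline: float = DEFAULT_BASELINE,
    amplitude: float = DEFAULT_AMPLITUDE,
    upstroke_center: float = DEFAULT_UPSTROKE_CENTER,
    upstroke_width: float = DEFAULT_UPSTROKE_WIDTH,
    repol_center: float = DEFAULT_REPOL_CENTER,
    repol_width: float = DEFAULT_REPOL_WIDTH,
) -> SourceField:
    """Spatial action-potential snapshot on a 1-D tissue line (mV)."""
    _check_support(grid, upstroke_center, upstroke_width, repol_center, repol_width)
    x = grid.coords()
    if grid.dimension != 1:
        raise ConfigurationError("grid must be one-dimensional")
    values = _template(x, baseline, amplitude, upstroke_center, upstroke_width,
                       repol_center, repol_width)
    return SourceField(values, grid)


def action_potential_profile_2d(
    grid: GridSpec,
    baseline: float = DEFAULT_BASELINE,
    amplitude: float = DEFAULT_AMPLITUDE,
    upstroke_center: float = DEFAULT_UPSTROKE_CENTER,
    upstroke_width: float = DEFAULT_UPSTROKE_WIDTH,
    repol_center: float = DEFAULT_REPOL_CENTER,
    repol_width: float = DEFAULT_REPOL_WIDTH,
    mode: str = "radial",
) -> SourceField:
    """Spatial action-potential snapshot on a 2-D tissue patch.

    ``radial`` mode is a depolarized disc centered on the origin: the rim
    sits at radius ``|upstroke_center|`` (the wavefront radius) and carries
    the gradual repolarization-edge profile, so the plateau fills the disc
    interior and the field decays to baseline outside; ``separable`` mode
    multiplies two 1-D templates.
    """
    if grid.dimension != 2:
        raise ConfigurationError("grid must be two-dimensional")
    _check_support(grid, upstroke_center, upstroke_width, repol_center, repol_width)
    pts = grid.coords()
    if mode == "radial":
        rho = np.hypot(pts[:, 0], pts[:, 1])
        rim = abs(upstroke_center)
        values = baseline + amplitude * ndtr((rim - rho) / repol_width)
    elif mode == "separable":
        tx = _template(pts[:, 0], 0.0, 1.0, upstroke_center, upstroke_width,
                       repol_center, repol_width)
        ty = _template(pts[:, 1], 0.0, 1.0, upstroke_center, upstroke_width,
                       repol_center, repol_width)
        values = baseline + amplitude * tx * ty
    else:
        raise ConfigurationError(f"unknown mode {mode!r}; use 'radial' or 'separable'")
    return SourceField(values, grid)


def delta_source(grid: GridSpec, position, amplitude: float = 1.0) -> SourceField:
    """Point (delta) source: full amplitude at the grid node nearest to position.

    Off-grid positions snap to the nearest node, ties broken toward the lower
    index.  Used in the ill-conditioning demonstration.
    """
    pos = np.atleast_1d(np.asarray(position, dtype=float))
    if pos.size != grid.dimension:
        raise DomainError(
            f"position has {pos.size} coordinate(s), grid is {grid.dimension}-D")
    half = grid.length_cm / 2.0
    if np.any(pos < -half) or np.any(pos > half):
        raise DomainError(f"position {pos} lies outside the tissue patch (±{half} cm)")
    ax = grid.axis_coords()

    def nearest(p: float) -> int:
        d = np.abs(ax - p)
        return int(np.argmin(d))  # argmin takes the first (lower) index on ties

    values = np.zeros(grid.n_nodes)
    if grid.dimension == 1:
        values[nearest(pos[0])] = amplitude
    else:
        ix, iy = nearest(pos[0]), nearest(pos[1])
        values[iy * grid.n_axis + ix] = amplitude
    return SourceField(values, grid)
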