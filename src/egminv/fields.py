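"""Potential fields sampled on the discretization grid."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DimensionMismatchError
from .grid import GridSpec

__all__ = ["SourceField", "ObservationField"]


def _validate(values: np.ndarray, grid: GridSpec, name: str) -> np.ndarray:
    values = np.asarray(values, dtype=float).ravel()
    if values.size != grid.n_nodes:
        raise DimensionMismatchError(
            f"{name} has {values.size} values but the grid has {grid.n_nodes} nodes"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{name} contains non-finite values")
    return values


@dataclass
class SourceField:
    """Transmembrane potential v_m (mV) at the source-plane nodes."""

    values: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.values = _validate(self.values, self.grid, "SourceField")

    def as_image(self) -> np.ndarray:
        """Reshape to (n, n) in 2-D; returns the flat vector in 1-D."""
        if self.grid.dimension == 2:
            n = self.grid.n_axis
            return self.values.reshape(n, n)
        return self.values


@dataclass
class ObservationField:
    """Extracellular potential v_e (mV) at the sensor-plane nodes (height z0)."""

    values: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.values = _validate(self.values, self.grid, "ObservationField")

    def as_image(self) -> np.ndarray:
        if self.grid.dimension == 2:
            n = self.grid.n_axis
            return self.values.reshape(n, n)
        return self.values
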