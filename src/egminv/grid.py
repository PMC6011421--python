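"""Discretization geometry for the source and sensor planes.

The model places a flat patch (or line) of cardiac tissue at ``z = 0`` and a
parallel plane (or line) of point sensors at the catchment height ``z = z0``.
Source and sensor grids share the same in-plane coordinates; each node is the
center of a square cell of side ``1/density`` cm, and the grid is symmetric
about the origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import GeometryError, GridError

__all__ = ["GridSpec", "PhysicalConstants"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the source/sensor planes.

    Parameters
    ----------
    dimension : {1, 2}
        1 for a tissue line, 2 for a square tissue patch.
    length_cm : float
        Extent of the tissue per axis in cm (default 3 cm).
    density : float
        Elements per cm per axis (default 80/cm).
    z0 : float
        Catchment height of the sensor plane above the tissue, in cm.
    decimation : int
        Subsampling factor per axis applied to the base grid, used to keep
        2-D problems tractable (the effective node spacing becomes
        ``decimation / density``).
    """

    dimension: int = 1
    length_cm: float = 3.0
    density: float = 80.0
    z0: float = 0.02
    decimation: int = 1

    def __post_init__(self) -> None:
        if self.dimension not in (1, 2):
            raise GridError(f"dimension must be 1 or 2, got {self.dimension}")
        if not self.length_cm > 0:
            raise GridError(f"length_cm must be positive, got {self.length_cm}")
        if not self.density > 0:
            raise GridError(f"density must be positive, got {self.density}")
        if not self.z0 > 0:
            raise GeometryError(f"catchment height z0 must be positive, got {self.z0}")
        if int(self.decimation) != self.decimation or self.decimation < 1:
            raise GridError(f"decimation must be a positive integer, got {self.decimation}")
        if self.n_axis < 2:
            raise GridError(
                f"degenerate grid: {self.n_axis} node(s) per axis after decimation"
            )

    @property
    def n_base_axis(self) -> int:
        """Number of elements per axis before decimation."""
        return int(round(self.length_cm * self.density))

    @property
    def n_base_nodes(self) -> int:
        """Total element count before decimation."""
        return self.n_base_axis ** self.dimension

    @property
    def n_axis(self) -> int:
        """Retained nodes per axis after decimation."""
        return len(range(0, self.n_base_axis, int(self.decimation)))

    @property
    def n_nodes(self) -> int:
        """Total retained node count."""
        return self.n_axis ** self.dimension

    @property
    def spacing(self) -> float:
        """Effective node spacing in cm (decimation folded in)."""
        return self.decimation / self.density

    @property
    def cell_measure(self) -> float:
        """Quadrature measure of one cell: spacing (1-D) or spacing**2 (2-D)."""
        return self.spacing ** self.dimension

    def axis_coords(self) -> np.ndarray:
        """Node-center coordinates along one axis, symmetric about the origin."""
        base = (np.arange(self.n_base_axis) + 0.5) / self.density - self.length_cm / 2.0
        return base[:: int(self.decimation)]

    def coords(self) -> np.ndarray:
        """All node coordinates.

        Returns shape ``(n_nodes,)`` in 1-D or ``(n_nodes, 2)`` in 2-D, with
        the x index varying fastest (row-major over (y, x)).
        """
        ax = self.axis_coords()
        if self.dimension == 1:
            return ax
        yy, xx = np.meshgrid(ax, ax, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel()])

    def with_(self, **changes) -> "GridSpec":
        """Return a copy with the given fields replaced."""
        from dataclasses import replace

        return replace(self, **changes)


@dataclass(frozen=True)
class PhysicalConstants:
    """Lumped physical constants of the quasielectrostatic model.

    The forward kernel scales with ``c = a^2 * sigma_i / (4 * sigma_e)`` where
    ``a`` is the cell (element) radius and ``sigma_i`` / ``sigma_e`` the
    intra- and extracellular conductivities.  Because realistic values for
    these are application-specific, ``c`` defaults to 1 (model units) and all
    potentials are then reported in the units of the transmembrane potential.
    """

    c: float = 1.0
    a: float | None = None
    sigma_i: float | None = None
    sigma_e: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.c) or self.c == 0:
            raise ValueError(f"gain c must be finite and nonzero, got {self.c}")
        micro = (self.a, self.sigma_i, self.sigma_e)
        if any(v is not None for v in micro):
            if any(v is None for v in micro):
                raise ValueError("a, sigma_i and sigma_e must be given together")
            expected = self.a**2 * self.sigma_i / (4.0 * self.sigma_e)
            if not np.isclose(self.c, expected, rtol=1e-12):
                raise ValueError(
                    f"inconsistent constants: c={self.c} but a^2*sigma_i/(4*sigma_e)={expected}"
                )

    @classmethod
    def from_cell(cls, a: float, sigma_i: float, sigma_e: float) -> "PhysicalConstants":
        """Build from microscopic parameters; c is derived."""
        return cls(c=a**2 * sigma_i / (4.0 * sigma_e), a=a, sigma_i=sigma_i, sigma_e=sigma_e)
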