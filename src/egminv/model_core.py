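"""Quasielectrostatic forward model for intracardiac electrograms.

A flat sheet of cardiac tissue at ``z = 0`` carries a transmembrane potential
``v_m``; a parallel sensor plane at height ``z0`` records the extracellular
potential ``v_e``.  In the quasielectrostatic approximation the two are linked
by a spatial convolution,

    v_e = h_e * v_m,      h_e(r) = lap Gamma(r)|_{z=z0},

where ``Gamma(r) = c / sqrt(|r|^2 + z0^2)`` is the 1/distance potential of a
unit element and ``lap`` is the in-plane (source-surface) Laplacian.  The
analytic impulse responses are

    1-D:  h(x)   = c (2 x^2  - z0^2) / (x^2  + z0^2)^{5/2}
    2-D:  h(rho) = c (rho^2 - 2 z0^2) / (rho^2 + z0^2)^{5/2}

Both are even/radially symmetric, negative at the origin and decay to zero, so
on a uniform grid the discretized operator ``H`` is a symmetric Toeplitz
matrix in 1-D and symmetric block-Toeplitz with Toeplitz blocks in 2-D.
Sources are assumed zero outside the patch, i.e. the convolution is truncated
with no wrap-around, and the Riemann cell measure (spacing, or spacing^2 in
2-D) is folded into ``H`` so the forward map is a plain matrix product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import toeplitz

from .exceptions import DimensionMismatchError, GeometryError, GridError
from .fields import ObservationField, SourceField
from .grid import GridSpec, PhysicalConstants

__all__ = [
    "gamma_potential",
    "impulse_response",
    "build_transfer_matrix",
    "forward",
    "TransferOperator",
]


def _check_z0(z0: float) -> None:
    if not z0 > 0:
        raise GeometryError(f"catchment height z0 must be positive, got {z0}")


def _radius2(offsets, dimension: int) -> np.ndarray:
    off = np.asarray(offsets, dtype=float)
    if dimension == 2:
        if off.shape == (2,):
            return np.sum(off**2)  # single point -> scalar
        if off.ndim < 1 or off.shape[-1] != 2:
            raise DimensionMismatchError(
                "2-D offsets must have the two in-plane components on the last axis"
            )
        return np.sum(off**2, axis=-1)
    return off**2


def gamma_potential(offsets, z0: float, constants: PhysicalConstants | None = None,
                    dimension: int = 1) -> np.ndarray:
    """Potential kernel Gamma at in-plane displacement(s) and height z0.

    ``Gamma = c / sqrt(|offset|^2 + z0^2)``; strictly positive for c > 0 and
    radially symmetric.
    """
    _check_z0(z0)
    c = (constants or PhysicalConstants()).c
    r2 = _radius2(offsets, dimension)
    return c / np.sqrt(r2 + z0**2)


def impulse_response(offsets, z0: float, constants: PhysicalConstants | None = None,
                     dimension: int = 1) -> np.ndarray:
    """In-plane Laplacian of Gamma evaluated at height z0.

    This is the spatial impulse response of the forward map: the electrogram
    produced at height ``z0`` by a point transmembrane source at the origin.
    """
    _check_z0(z0)
    c = (constants or PhysicalConstants()).c
    r2 = _radius2(offsets, dimension)
    if dimension == 2:
        num = r2 - 2.0 * z0**2
    else:
        num = 2.0 * r2 - z0**2
    return c * num / (r2 + z0**2) ** 2.5


def impulse_response_radial(distances, z0: float,
                            constants: PhysicalConstants | None = None,
                            dimension: int = 1) -> np.ndarray:
    """Impulse response as a function of scalar distance (radial profile)."""
    d = np.abs(np.asarray(distances, dtype=float))
    if dimension == 2:
        # feed the radius through the 2-D radial form
        return impulse_response(np.stack([d, np.zeros_like(d)], axis=-1), z0,
                                constants, dimension=2)
    return impulse_response(d, z0, constants, dimension=1)


@dataclass
class TransferOperator:
    """Discretized forward operator ``v_e = H v_m``.

    Attributes
    ----------
    impulse : ndarray
        Sampled impulse response over signed grid offsets: shape ``(2n-1,)``
        in 1-D, ``(2m-1, 2m-1)`` in 2-D (``n``/``m`` nodes per axis).  Entry
        for offset 0 sits at the center.  The matrix is rebuilt from this
        array, so perturbing it preserves the (block-)Toeplitz structure.
    matrix : ndarray
        Dense ``H`` (n_sensors x n_sources), cell measure folded in.
    """

    impulse: np.ndarray
    matrix: np.ndarray
    grid: GridSpec
    constants: PhysicalConstants
    _svd: tuple | None = field(default=None, repr=False, compare=False)

    @classmethod
    def from_impulse(cls, impulse: np.ndarray, grid: GridSpec,
                     constants: PhysicalConstants) -> "TransferOperator":
        """Rebuild the dense matrix from a signed-offset impulse sample."""
        impulse = np.asarray(impulse, dtype=float)
        n = grid.n_axis
        if grid.dimension == 1:
            if impulse.shape != (2 * n - 1,):
                raise DimensionMismatchError(
                    f"impulse must have shape {(2 * n - 1,)}, got {impulse.shape}")
            center = n - 1
            col = impulse[center:]            # offsets 0 .. +(n-1)
            row = impulse[center::-1]         # offsets 0 .. -(n-1)
            H = toeplitz(col, row) * grid.cell_measure
        else:
            if impulse.shape != (2 * n - 1, 2 * n - 1):
                raise DimensionMismatchError(
                    f"impulse must have shape {(2*n-1, 2*n-1)}, got {impulse.shape}")
            idx = np.arange(n)
            S = idx[:, None] - idx[None, :] + (n - 1)   # signed offset index
            H4 = impulse[S[:, None, :, None], S[None, :, None, :]]
            H = H4.reshape(n * n, n * n) * grid.cell_measure
        return cls(impulse=impulse, matrix=H, grid=grid, constants=constants)

    def svd(self):
        """Cached singular value decomposition of H."""
        if self._svd is None:
            self._svd = np.linalg.svd(self.matrix, full_matrices=False)
        return self._svd

    def save(self, path) -> None:
        """Serialize to a portable .npz (impulse + grid metadata; H rebuilt on load)."""
        g = self.grid
        np.savez(
            path,
            impulse=self.impulse,
            dimension=g.dimension, length_cm=g.length_cm, density=g.density,
            z0=g.z0, decimation=g.decimation, c=self.constants.c,
        )

    @classmethod
    def load(cls, path) -> "TransferOperator":
        with np.load(path) as data:
            grid = GridSpec(
                dimension=int(data["dimension"]), length_cm=float(data["length_cm"]),
                density=float(data["density"]), z0=float(data["z0"]),
                decimation=int(data["decimation"]),
            )
            constants = PhysicalConstants(c=float(data["c"]))
            return cls.from_impulse(data["impulse"], grid, constants)


def build_transfer_matrix(grid: GridSpec,
                          constants: PhysicalConstants | None = None) -> TransferOperator:
    """Sample the impulse response on the grid and assemble H.

    ``H[i, j] = h_e(r_i - r_j) * cell_measure`` — each row is the (truncated)
    shifted impulse response, so H is symmetric Toeplitz in 1-D and symmetric
    BTTB in 2-D.
    """
    constants = constants or PhysicalConstants()
    n = grid.n_axis
    if n < 2:
        raise GridError("degenerate grid: fewer than 2 nodes per axis")
    dx = grid.spacing
    signed = np.arange(-(n - 1), n) * dx
    if grid.dimension == 1:
        # evaluate on |offset| so the sample is even to the last bit
        impulse = impulse_response(np.abs(signed), grid.z0, constants, dimension=1)
    else:
        rho = np.hypot(np.abs(signed)[:, None], np.abs(signed)[None, :])
        impulse = impulse_response_radial(rho, grid.z0, constants, dimension=2)
    return TransferOperator.from_impulse(impulse, grid, constants)


def forward(source: SourceField, T: TransferOperator) -> ObservationField:
    """Forward map: extracellular potentials at the sensors, ``v_e = H v_m``."""
    if source.grid != T.grid:
        raise DimensionMismatchError("source grid does not match transfer-operator grid")
    return ObservationField(T.matrix @ source.values, T.grid)
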