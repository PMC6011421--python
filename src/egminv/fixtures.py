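"""Small seeded end-to-end instances for tests and demos."""

from __future__ import annotations

import numpy as np

from .exceptions import ParameterError
from .fields import SourceField
from .grid import GridSpec
from .model_core import build_transfer_matrix, forward
from .sources import action_potential_profile_1d, delta_source

__all__ = ["make_fixture"]


def make_fixture(size: int = 16, kind: str = "ap", seed: int = 0,
                 z0: float = 0.02):
    """Build a fast 1-D test instance.

    Returns ``(grid, source, transfer, observations)`` on a 3-cm line with
    ``size`` nodes.  ``kind`` selects the source: the action-potential
    template (``ap``), a centered delta (``delta``), or uniform random values
    in [0, 100] mV (``random``).  Identical seeds give identical fixtures.
    """
    if size < 8:
        raise ParameterError(f"fixture needs at least 8 nodes, got {size}")
    grid = GridSpec(dimension=1, length_cm=3.0, density=size / 3.0, z0=z0)
    if kind == "ap":
        src = action_potential_profile_1d(grid)
    elif kind == "delta":
        src = delta_source(grid, 0.0, amplitude=100.0)
    elif kind == "random":
        rng = np.random.default_rng(seed)
        src = SourceField(rng.uniform(0.0, 100.0, grid.n_nodes), grid)
    else:
        raise ParameterError(f"unknown fixture kind {kind!r}")
    T = build_transfer_matrix(grid)
    return grid, src, T, forward(src, T)
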