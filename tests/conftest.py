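import numpy as np
import pytest

from egminv import GridSpec, PhysicalConstants, build_transfer_matrix, forward
from egminv.sources import action_potential_profile_1d


@pytest.fixture(scope="session")
def grid64():
    """64-node 1-D line, 3 cm, z0 = 0.02 cm."""
    return GridSpec(dimension=1, length_cm=3.0, density=64 / 3.0, z0=0.02)


@pytest.fixture(scope="session")
def model64(grid64):
    """Small end-to-end 1-D instance: (grid, source, transfer, observations)."""
    src = action_potential_profile_1d(grid64)
    T = build_transfer_matrix(grid64)
    return grid64, src, T, forward(src, T)


@pytest.fixture(scope="session")
def grid2d_small():
    """12x12 2-D patch."""
    return GridSpec(dimension=2, length_cm=3.0, density=4.0, z0=0.02)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
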