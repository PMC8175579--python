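import numpy as np
import pytest

from gomflux.hydrography import DensityProfile, MixingParams
from gomflux.synthetic_data import SimulationConfig


@pytest.fixture
def params():
    return MixingParams()


@pytest.fixture
def stable_profile():
    z = np.arange(0.0, 50.0, 1.0)
    return DensityProfile("stable", "t0", z, 23.0 + 0.01 * z)


@pytest.fixture
def five_point_profile():
    """Depths 1..5 m, one interior inversion; displacements [0,+2,-1,-1,0]."""
    return DensityProfile("five", "t0", np.arange(1.0, 6.0),
                          np.array([1025.0, 1025.3, 1025.1, 1025.2, 1025.4]))


@pytest.fixture
def sim_config():
    return SimulationConfig(seed=42)


def brute_force_displacements(depth, sigma):
    """Independent O(n^2)-style oracle: stable ascending sort of sigma by
    (value, original index); displacement = new-position depth - own depth."""
    order = sorted(range(len(sigma)), key=lambda i: (sigma[i], i))
    disp = np.empty(len(depth))
    for newpos, orig in enumerate(order):
        disp[orig] = depth[newpos] - depth[orig]
    return disp
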