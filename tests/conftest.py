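import numpy as np
import pytest

from pdekit.geometry import BoxDomain, grid_particles, jitter_particles, neighbor_search


@pytest.fixture(scope="session")
def unit_lattice_21():
    return grid_particles(BoxDomain((0.0, 0.0), (1.0, 1.0)), 21)


@pytest.fixture(scope="session")
def jittered_21():
    ps = grid_particles(BoxDomain((0.0, 0.0), (1.0, 1.0)), 21)
    return jitter_particles(ps, 0.2, seed=1)


@pytest.fixture(scope="session")
def jittered_21_nbrs(jittered_21):
    return neighbor_search(jittered_21, 3.1 * jittered_21.h_nominal)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
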