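import numpy as np
import pytest

from cytodiffuse.network import Filament, NetworkRealization, NetworkSpec, generate_network


@pytest.fixture(scope="session")
def cortical_net():
    """One reference network at cortical density (1430 filaments/μm³)."""
    return generate_network(NetworkSpec(1430, seed=1))


@pytest.fixture(scope="session")
def sparse_net():
    """A light network for cheap geometric tests."""
    return generate_network(NetworkSpec(200, seed=4))


def make_net(filaments, box_edge=1.0, seed=0):
    """Hand-built realization from (p0, p1, radius[, parent, angle]) tuples."""
    fils = []
    for rec in filaments:
        p0, p1, r = np.asarray(rec[0], float), np.asarray(rec[1], float), rec[2]
        parent = rec[3] if len(rec) > 3 else None
        angle = rec[4] if len(rec) > 4 else None
        fils.append(Filament(p0, p1, r, parent, angle))
    return NetworkRealization(fils, box_edge, seed)


@pytest.fixture
def two_parallel_net():
    """Two parallel filaments with aligned midpoints 0.05 μm apart."""
    return make_net([
        ((0.2, 0.40, 0.1), (0.8, 0.40, 0.9), 0.005),
        ((0.2, 0.45, 0.1), (0.8, 0.45, 0.9), 0.005),
    ])
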