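import numpy as np
import pytest

import stentsim as ss


@pytest.fixture
def tiny_geometry():
    """0.2 mm long artery, radii 0.1/0.2 mm — a few hundred sites."""
    return ss.Geometry(length=0.2, r_inner=0.1, r_outer=0.2, stent_z=(0.05, 0.15))


@pytest.fixture
def small_geometry():
    """2 mm long artery at coarse spacing — fast full-pipeline runs."""
    return ss.Geometry(length=2.0, r_inner=0.5, r_outer=0.75, stent_z=(0.5, 1.5))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def block_lattice():
    """A solid 9x9x9 all-wall block with intact ECM (no artery geometry):
    convenient for single-cell rule tests away from boundaries."""
    lat = ss.Lattice.empty((9, 9, 9), np.zeros(3), 0.01825)
    lat.domain[:] = ss.WALL
    lat.ecm[:] = 1.0
    return lat


def make_wall_block(n=9, dl=0.01825, ecm=1.0):
    lat = ss.Lattice.empty((n, n, n), np.zeros(3), dl)
    lat.domain[:] = ss.WALL
    lat.ecm[:] = ecm
    return lat
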