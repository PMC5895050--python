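import numpy as np
import pytest

from torgo.fixtures import (FixtureSpec, make_chain, make_frame_rotation_fixture,
                            make_ring_fixture)
from torgo.minimizer import PotentialConfig


def random_multipole(rng, mu_scale=0.5, theta_scale=1.0):
    """(q, mu, theta) triple with a traceless symmetric quadrupole."""
    A = rng.uniform(-theta_scale, theta_scale, (3, 3))
    th = 0.5 * (A + A.T)
    th -= np.eye(3) * np.trace(th) / 3
    return (float(rng.uniform(-1, 1)), rng.uniform(-mu_scale, mu_scale, 3), th)


@pytest.fixture(scope="session")
def chain_fixture():
    """Mid-sized branched polymer with full multipoles (reduced units)."""
    return make_chain(FixtureSpec(n_units=12, seed=3))


@pytest.fixture(scope="session")
def small_chain():
    return make_chain(FixtureSpec(n_units=5, seed=8))


@pytest.fixture(scope="session")
def ring_fixture():
    return make_ring_fixture(FixtureSpec(n_units=7, seed=2, include_ring=True))


@pytest.fixture(scope="session")
def frame_rotation_fixture():
    return make_frame_rotation_fixture(seed=1)


@pytest.fixture
def reduced_cfg():
    return PotentialConfig(prefactor=1.0, gamma=0.0)


@pytest.fixture
def sasa_cfg():
    return PotentialConfig(elec_weight=0.0, gamma=1.0, probe=1.4)
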