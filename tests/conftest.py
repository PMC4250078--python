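import numpy as np
import pytest

from mechanotrace import FixtureConfig, gen_harmonic_dimer, gen_membrane_protein_fixture


@pytest.fixture(scope="session")
def small_fixture():
    """Default-geometry fixture with a shorter time window for fast unit tests."""
    config = FixtureConfig(n_frames=120)
    traj, truth = gen_membrane_protein_fixture(config, seed=1)
    return traj, truth, config


@pytest.fixture()
def dimer():
    return gen_harmonic_dimer(separation=1.5, stiffness=100.0, rest_length=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
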