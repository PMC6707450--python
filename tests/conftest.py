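import numpy as np
import pytest

from mitonet import calibrate_replication_control


@pytest.fixture(scope="session")
def nominal_params():
    """Desk-scale nominal parameterization: n_ss=1000, fs_ss=0.5,
    mu=0.023/day, network magnitude M=0.1."""
    return calibrate_replication_control(M=0.1)


@pytest.fixture(scope="session")
def small_params():
    """Smaller cell (n_ss=250) for cheap stochastic checks."""
    return calibrate_replication_control(M=0.1, n_target=250)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
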