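import numpy as np
import pytest

from sweepnet.config import default_params


@pytest.fixture(scope="session")
def params_small():
    """Control parameters on a coarse grid for fast unit tests."""
    return default_params(101)


@pytest.fixture(scope="session")
def params_medium():
    return default_params(201)


@pytest.fixture(scope="session")
def pair20_medium(params_medium):
    """Shared control +-20 oct/s sweep pair on the 201-point grid."""
    from sweepnet.protocols import run_sweep_pair

    return run_sweep_pair(params_medium, 20.0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
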