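import numpy as np
import pytest

from megdcm.network_models import build_model
from megdcm.nmm_core import ModelParameters


@pytest.fixture(scope="session")
def spec2():
    return build_model(2)


@pytest.fixture(scope="session")
def spec1():
    return build_model(1)


@pytest.fixture(scope="session")
def params2(spec2):
    return ModelParameters.default(spec2)


@pytest.fixture(scope="session")
def t_epoch():
    """Default full epoch grid, 1 ms."""
    return np.arange(-100.0, 1000.5, 1.0)


@pytest.fixture(scope="session")
def t_fit():
    """Scaled-down fitting grid: -100..500 ms at 2 ms."""
    return np.arange(-100.0, 500.1, 2.0)
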