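import numpy as np
import pytest

from truespin import ax_benchmark, Simulator
from truespin.fixtures import ENCODING_GRID_S, ax_relaxation_study


@pytest.fixture(scope="session")
def grid():
    return np.array(ENCODING_GRID_S)


@pytest.fixture(scope="session")
def ax10():
    return ax_benchmark(10.0)


@pytest.fixture(scope="session")
def ax0():
    return ax_benchmark(0.0)


@pytest.fixture(scope="session")
def sim_ax10(ax10):
    return Simulator(ax10)


@pytest.fixture(scope="session")
def study_j10():
    """Fitted rates of the three experiments on the coupled benchmark."""
    return ax_relaxation_study(10.0)


@pytest.fixture(scope="session")
def study_j0():
    return ax_relaxation_study(0.0)
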