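import numpy as np
import pytest

from calbeta import DoseParams, InjectionProtocol, ScalingParams


@pytest.fixture(scope="session")
def small():
    return DoseParams.small_doses()


@pytest.fixture(scope="session")
def large():
    return DoseParams.large_doses()


@pytest.fixture(scope="session")
def frozen_unit_dose():
    """Constant 1 ug/ml drive: the autonomous mode used for bifurcation work."""
    return InjectionProtocol(a=1.0, frozen=True)


@pytest.fixture(scope="session")
def scaling():
    return ScalingParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
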