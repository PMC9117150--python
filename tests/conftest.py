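import numpy as np
import pytest

from chromech import (
    CriticalForceDistribution,
    HWLCAssembly,
    WLCElement,
)


@pytest.fixture
def wlc():
    return WLCElement(f_c=10.0, ell=1.0)


@pytest.fixture
def power_dist():
    return CriticalForceDistribution.power_law(0.86, 5.0, 500.0)


@pytest.fixture
def exp_dist():
    return CriticalForceDistribution.exponential(160.0, 5.0, 500.0)


@pytest.fixture
def small_assembly():
    return HWLCAssembly(f_c=np.array([10.0, 100.0]), ell=np.array([0.5, 0.5]))
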