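import numpy as np
import pytest
from hypothesis import settings

from ztlkinetics import DegradationParams, LightSchedule

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def wt_params():
    """In-vivo-refined wild-type parameter set (k1 from LL, k2 dark max)."""
    return DegradationParams(k1=0.14, k2=0.8, k3=0.7)


@pytest.fixture
def g80r_params():
    """Slow-photocycle variant: same degradation rates, ~4.7x slower reversion."""
    return DegradationParams(k1=0.14, k2=0.8, k3=0.15)


@pytest.fixture
def prediction_params():
    """Parameter set with the published-model light-state bound k1 = 0.2."""
    return DegradationParams(k1=0.2, k2=0.8, k3=0.7)


@pytest.fixture
def ld_schedule():
    return LightSchedule.ld()


@pytest.fixture
def dark_times():
    """Hourly sampling through the first dark phase, ZT12-ZT24."""
    return np.arange(12.0, 24.0 + 1e-9, 1.0)
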