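import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pfhaqlink.irt import ItemParams, QuadratureGrid

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_items():
    """Three small polytomous items, enumerable by brute force."""
    return [
        ItemParams("t1", thresholds=np.array([-1.0, 1.0])),
        ItemParams("t2", thresholds=np.array([-0.5, 0.5])),
        ItemParams("t3", thresholds=np.array([0.0, 1.5])),
    ]


@pytest.fixture(scope="session")
def symmetric_items():
    """Item set symmetric about theta = 0."""
    return [
        ItemParams("s1", thresholds=np.array([-1.0, 1.0])),
        ItemParams("s2", thresholds=np.array([-0.5, 0.5])),
    ]


@pytest.fixture(scope="session")
def grid61():
    return QuadratureGrid.make(61, 6.0)
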