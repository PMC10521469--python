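import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_trace():
    """10 s of still gravity at 30 Hz starting on a round second."""
    from accelbalance import RawTrace

    n = 300
    return RawTrace(
        start=pd.Timestamp("2024-01-01 08:00:00"),
        sample_rate=30,
        x=np.zeros(n),
        y=np.zeros(n),
        z=np.ones(n),
    )
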