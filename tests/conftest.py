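import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from tripdose import SegmentSpec, SessionScenario


@pytest.fixture
def two_segment_scenario():
    """Noiseless two-microenvironment session with contrasting levels."""
    return SessionScenario(
        segments=[
            SegmentSpec("bus", 2000, 87.0, 28.2, 5.0, 300.0),
            SegmentSpec("pedestrian", 2000, 40.0, 10.0, 1.0, 2500.0),
        ],
        noise_cv=0.0,
        k_true=0.005,
        photometric_factor_true=0.63,
        seed=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
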