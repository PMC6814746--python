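import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_trace(intensities, frame_interval=2.0, **kwargs):
    """Build a FluorescenceTrace on a uniform grid starting at t=0."""
    from caspike import FluorescenceTrace

    intensities = np.asarray(intensities, dtype=float)
    defaults = dict(plant_id="p1", cell_id="c1", channel="nuclear")
    defaults.update(kwargs)
    return FluorescenceTrace(
        times=np.arange(intensities.size) * frame_interval,
        intensities=intensities,
        frame_interval=frame_interval,
        **defaults,
    )
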