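import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tdluquant import SlideFrame, SlideSpec, generate_slide

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_slide():
    """A 1024^2 synthetic slide at 2 um/px with 6 TDLUs, fixed seed."""
    spec = SlideSpec(
        frame=SlideFrame(1024, 1024, 2.0), n_tdlus=6, seed=11
    )
    return generate_slide(spec)


@pytest.fixture
def tiny_frame():
    return SlideFrame(64, 64, 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
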