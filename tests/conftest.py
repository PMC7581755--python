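import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def quiet_scene():
    """Factory for small noise-free scenes used across imaging/tracking tests."""
    from larvatrack import SceneConfig

    def make(**kwargs):
        defaults = dict(
            width_px=80,
            height_px=120,
            pixel_scale=0.1,
            duration_s=1.0,
            fps=5.0,
            noise_sd=0.0,
            seed=0,
        )
        defaults.update(kwargs)
        return SceneConfig(**defaults)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
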