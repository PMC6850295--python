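import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gradthresh import SceneParams, generate_scene

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_scene():
    """Nuclei-like scene at the generator defaults (smaller field for speed)."""
    return generate_scene(SceneParams(shape=(192, 192), n_objects=8, seed=0))


@pytest.fixture(scope="session")
def ramp_scene():
    """Two blobs of unequal intensity under a linear illumination ramp."""
    return generate_scene(
        SceneParams(
            shape=(224, 224),
            n_objects=2,
            radius_range=(13, 15),
            fg_values=[60, 120],
            centers=[(112, 45), (112, 179)],
            ramp=40,
            seed=3,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
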