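import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from aphiddrs.bands import SENTINEL2B_WORKING
from aphiddrs.synthetic import (
    SceneConfig,
    endmember_band_vectors,
    generate_ground_points,
    simulate_scene,
)


@pytest.fixture(scope="session")
def band_set():
    return SENTINEL2B_WORKING


@pytest.fixture(scope="session")
def grid():
    return np.arange(325.0, 1076.0, 1.0)


@pytest.fixture(scope="session")
def endmembers():
    """Resampled endmember band vectors (healthy, grade0..4, scene classes)."""
    return endmember_band_vectors()


@pytest.fixture(scope="session")
def noisefree_bundle():
    """Small noise-free scene with truth maps."""
    return simulate_scene(SceneConfig(rows=48, cols=48, noise_sd=0.0, seed=7))


@pytest.fixture(scope="session")
def noisefree_points(noisefree_bundle):
    return generate_ground_points(noisefree_bundle, seed=7)


@pytest.fixture(scope="session")
def default_bundle():
    """Default-conditions scene (with sensor noise)."""
    return simulate_scene(SceneConfig(seed=3))


@pytest.fixture(scope="session")
def default_points(default_bundle):
    return generate_ground_points(default_bundle, seed=3)
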