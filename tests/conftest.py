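import numpy as np
import pytest

from pacarbon import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def small_config() -> SceneConfig:
    """A desk-sized scene: 80 km square, 125 m fine pixels, 12 PAs."""
    return SceneConfig(width=80, height=80, subdivision=8, n_pas=12,
                       pa_area_range_km2=(10.0, 200.0), n_outliers=2, seed=3)


@pytest.fixture(scope="session")
def small_scene(small_config):
    return generate_scene(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20231108)
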