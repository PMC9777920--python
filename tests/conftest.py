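import numpy as np
import pytest

from cornimpurity.synthetic import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def clean_scene():
    """One full-size clean scene shared by tests that only read it."""
    return generate_scene(SceneConfig(seed=1))


@pytest.fixture(scope="session")
def empty_scene():
    """A scene with no impurities at all."""
    return generate_scene(
        SceneConfig(seed=7, n_bracts=0, n_corncobs=0, n_stones=0)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
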