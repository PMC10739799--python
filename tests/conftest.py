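import numpy as np
import pytest

from gobletseg.synthetic import SceneParams, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic 128x128 scene with defaults."""
    return generate_scene(SceneParams(width_px=128, height_px=128, seed=42))


@pytest.fixture(scope="session")
def isolated_scene():
    """Scene without clustering: every cell is its own component."""
    return generate_scene(
        SceneParams(width_px=128, height_px=128, cluster_prob=0.0, seed=7)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
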