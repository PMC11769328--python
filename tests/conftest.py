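import numpy as np
import pytest

from hyperseed.envi import SpectralCube
from hyperseed.synthetic import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def small_scene_spec():
    """A 2x2-seed scene: full layout, fast to render."""
    return SceneSpec(grid_rows=2, grid_cols=2,
                     protein_pct=[8.0, 12.0, 16.0, 19.0],
                     noise_sd=0.0, rng_seed=11)


@pytest.fixture(scope="session")
def small_scene(small_scene_spec):
    return generate_scene(small_scene_spec)


@pytest.fixture
def random_cube():
    rng = np.random.default_rng(42)
    data = rng.uniform(0, 1, (8, 8, 5))
    return SpectralCube(data, np.linspace(400, 480, 5))
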