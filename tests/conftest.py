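import numpy as np
import pytest

from sheetscan import SceneParams, render_scene


@pytest.fixture(scope="session")
def small_scene():
    """512-px scene with 30 cells and 2 debris, fixed seed."""
    return render_scene(
        SceneParams(width_px=512, height_px=512, n_cells=30, n_debris=2, seed=3)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
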