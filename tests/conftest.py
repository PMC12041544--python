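import numpy as np
import pytest

import canopymap as cm


@pytest.fixture(scope="session")
def cfg2013():
    return cm.load_year_config("2013")


@pytest.fixture(scope="session")
def small_scene():
    """Calibrated 192x192 scene with truth and bookkeeping (session-cached)."""
    spec = cm.default_scene_spec(height=192, width=192, layout_seed=7)
    img, truth, book = cm.generate_scene(spec)
    return spec, img, truth, book


@pytest.fixture
def flat_image():
    """Uniform mid-gray 4-band image (no texture, no classes of interest)."""
    bands = np.full((4, 16, 16), 100, dtype=np.uint8)
    return cm.MultibandImage(bands=bands)


def make_image(red, green, blue, nir, **kwargs):
    """Single-valued image helper: each band one constant, shape 8x8."""
    bands = np.zeros((4, 8, 8), dtype=np.float64)
    for i, v in enumerate((red, green, blue, nir)):
        bands[i] = v
    return cm.MultibandImage(bands=bands.astype(np.uint8), **kwargs)
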