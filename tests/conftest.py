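import numpy as np
import pytest
from hypothesis import settings

import pillchroma as pc

settings.register_profile("ci", derandomize=True, max_examples=60,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog():
    return pc.build_catalog(seed=0)


@pytest.fixture(scope="session")
def grid():
    return pc.condition_grid()


@pytest.fixture(scope="session")
def reference():
    return pc.reference_condition()


@pytest.fixture(scope="session")
def noise_free():
    return pc.RenderParams(noise_sigma=0.0)


@pytest.fixture(scope="session")
def reference_record(catalog, reference):
    """One default rendered frame under the reference condition."""
    return pc.render_image(catalog[0], reference, (128, 128), seed=11)


def draw_disk(shape, center, radius, fg=200, bg=10):
    """8-bit RGB frame with a uniform disk; returns (image, truth mask)."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2
    img = np.full((h, w, 3), bg, dtype=np.uint8)
    img[mask] = fg
    return img, mask
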