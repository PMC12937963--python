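import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from wedseg.synthetic import SyntheticConfig, generate_pair  # noqa: E402

NUCLEUS_RGB = (90, 50, 130)
BACKGROUND_RGB = (235, 190, 215)


@pytest.fixture(scope="session")
def easy_config():
    """Small, well-separated nuclei with mild noise; every nucleus survives
    the distance-core thresholding because radii are nearly uniform."""
    return SyntheticConfig(height=64, width=64, n_nuclei=3,
                           radius_range=(7, 9), eccentricity_range=(0.0, 0.3),
                           overlap_fraction=0.0, noise_sigma=4.0, seed=0)


@pytest.fixture(scope="session")
def easy_pair(easy_config):
    return generate_pair(easy_config)


def disc_image(size=128, centers=((64, 56), (64, 72)), radius=10,
               fg=NUCLEUS_RGB, bg=BACKGROUND_RGB):
    """Noise-free scene of exact discs; geometry chosen analytically."""
    img = np.full((size, size, 3), bg, dtype=np.uint8)
    yy, xx = np.mgrid[0:size, 0:size]
    for cy, cx in centers:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius * radius] = fg
    return img


@pytest.fixture(scope="session")
def touching_nuclei_image():
    """Two radius-10 discs, centers 16 px apart: one fused blob whose
    distance-transform neck (half-width 6) falls below 0.7 * 10, so the
    watershed must split it."""
    return disc_image(centers=((64, 56), (64, 72)), radius=10)


@pytest.fixture(scope="session")
def separated_nuclei_image():
    """Two well-separated radius-10 discs."""
    return disc_image(centers=((40, 40), (90, 90)), radius=10)
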