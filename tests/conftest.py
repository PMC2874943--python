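import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import eyemodel as em

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

DISK_CENTER = (64.0, 64.0)
DISK_RADIUS = 40.0


@pytest.fixture(scope="session")
def disk_fixture():
    """128x128 noise-free disk image with its analytic circle contour."""
    image, circle = em.generate_disk_image(128, 128, DISK_CENTER, DISK_RADIUS)
    return image, circle


@pytest.fixture(scope="session")
def disk_init_mask():
    """Initial region: a box hugging the disk (8 px margin)."""
    mask = np.zeros((128, 128), dtype=bool)
    mask[16:113, 16:113] = True
    return mask


@pytest.fixture(scope="session")
def eye_slice():
    """Noise-free eye phantom at a 30 degree axis."""
    return em.generate_eye_slice(256, 256, axis_angle=30.0,
                                 noise_sigma=0.0, seed=1)


@pytest.fixture(scope="session")
def sphere_profile():
    """Pole-to-pole semicircle profile of a radius-10 sphere."""
    R = 10.0
    u = np.linspace(-R, R, 101)
    r = np.sqrt(np.maximum(R * R - u * u, 0.0))
    return np.column_stack([u, r]), R


@pytest.fixture(scope="session")
def x_axis():
    return em.SymmetryAxis(point=np.zeros(2), direction=np.array([1.0, 0.0]))


@pytest.fixture(scope="session")
def lens_mesh():
    """Biconvex lens surface: 4 mm thick, 10 mm diameter."""
    return em.generate_biconvex_mesh(9, 16, 4.0, 10.0)


def circle_sdf(n=128, center=(64.0, 64.0), radius=40.0):
    xs, ys = np.meshgrid(np.arange(n), np.arange(n))
    return np.hypot(xs - center[0], ys - center[1]) - radius
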