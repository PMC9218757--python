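import numpy as np
import pytest

from rgbdfruit.rgbd_io import DepthImage, PipelineConfig, RgbImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def config():
    return PipelineConfig()


def make_sphere_depth(height=200, width=240, center=(100, 120), radius=50.0,
                      z_center=2000.0, background=2600.0, mm_per_px=2.0,
                      noise_sd=0.0, hole_fraction=0.0, rng=None):
    """Minimal convex-fruit depth frame used across tests."""
    rr, cc = np.meshgrid(np.arange(height, dtype=float),
                         np.arange(width, dtype=float), indexing="ij")
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    depth = np.full((height, width), background)
    inside = d2 < radius ** 2
    depth[inside] = z_center - mm_per_px * np.sqrt(radius ** 2 - d2[inside])
    if noise_sd > 0:
        depth = depth + rng.normal(0, noise_sd, depth.shape)
    if hole_fraction > 0:
        depth[rng.random(depth.shape) < hole_fraction] = 0.0
    return DepthImage.from_raw(depth)


def disc_mask(shape, center, radius):
    rr, cc = np.meshgrid(np.arange(shape[0], dtype=float),
                         np.arange(shape[1], dtype=float), indexing="ij")
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


@pytest.fixture
def flat_rgb():
    return RgbImage(np.full((60, 80, 3), 100, dtype=np.uint8))
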