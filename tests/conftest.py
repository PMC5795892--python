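import numpy as np
import pytest

from visceraseg.data_model import CameraIntrinsics, RGBDImage
from visceraseg.synthetic import SceneConfig


@pytest.fixture
def intrinsics():
    return CameraIntrinsics(fx=150.0, fy=150.0, cx=79.5, cy=59.5)


@pytest.fixture
def small_scene_config():
    """Quarter-resolution scene distribution used throughout the tests."""
    return SceneConfig(height=120, width=160, seed=0)


@pytest.fixture
def flat_image(intrinsics):
    """Constant-depth, uniform-color 120x160 frame."""
    rgb = np.full((120, 160, 3), 128, dtype=np.uint8)
    depth = np.full((120, 160), 0.35)
    return RGBDImage(rgb=rgb, depth=depth, intrinsics=intrinsics)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
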