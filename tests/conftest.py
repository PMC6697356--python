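import numpy as np
import pytest

from rgbdclean import CameraIntrinsics, ColorImage, DepthImage, RigidTransform


@pytest.fixture
def K_vga() -> CameraIntrinsics:
    """640x480 sensor with the focal length used in the worked examples."""
    return CameraIntrinsics(fx=500.0, fy=500.0, cx=320.0, cy=240.0, width=640, height=480)


def make_intrinsics(w: int, h: int, f: float = 100.0) -> CameraIntrinsics:
    return CameraIntrinsics(fx=f, fy=f, cx=w / 2.0, cy=h / 2.0, width=w, height=h)


def random_frame(rng: np.random.Generator, w: int = 16, h: int = 16, p_invalid: float = 0.2):
    """A random organized depth + color frame on a small grid."""
    depth = rng.uniform(0.3, 2.0, size=(h, w))
    depth[rng.random((h, w)) < p_invalid] = 0.0
    color = rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)
    return DepthImage(depth), ColorImage(color)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def baseline_transform() -> RigidTransform:
    """2.5 cm horizontal stereo baseline between depth and color sensors."""
    return RigidTransform(np.eye(3), np.array([0.025, 0.0, 0.0]))
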