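import numpy as np
import pytest

from microclot import CONTROL_TRUTH, KineticsTruth, RenderConfig


def iou(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    return float((a & b).sum() / (a | b).sum())


def disc_image(shape=(200, 200), center=(100, 100), radius=60,
               background=200.0, foreground=100.0) -> tuple[np.ndarray, np.ndarray]:
    """Uniform background with one darker disc; returns (image, disc mask)."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    disc = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    img = np.full(shape, background, dtype=float)
    img[disc] = foreground
    return img, disc


@pytest.fixture
def control_truth() -> KineticsTruth:
    return CONTROL_TRUTH


@pytest.fixture
def small_cfg() -> RenderConfig:
    """Fast rendering geometry used throughout the suite."""
    return RenderConfig(image_size=(128, 128), clot_radius=40,
                        frame_interval_h=4.0, duration_h=168.0, seed=7)
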