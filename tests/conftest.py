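import numpy as np
import pytest

from temflow.preprocess import FieldImage
from temflow.synth import SceneParams, generate_scene


def disc_mask(radius: int, pad: int = 10) -> np.ndarray:
    """Solid digital disc (pixel centres within radius+0.5 of the centre)."""
    size = 2 * (radius + pad)
    yy, xx = np.mgrid[:size, :size]
    c = size / 2 - 0.5
    return (yy - c) ** 2 + (xx - c) ** 2 <= (radius + 0.5) ** 2


def rect_mask(height: int, width: int, pad: int = 10) -> np.ndarray:
    mask = np.zeros((height + 2 * pad, width + 2 * pad), dtype=bool)
    mask[pad:pad + height, pad:pad + width] = True
    return mask


@pytest.fixture(scope="session")
def small_scene():
    """A small non-touching scene used by several modules (8 cells/class)."""
    params = SceneParams(field_size_px=(256, 256), n_attached=8,
                         n_transmigrated=8, n_debris=5, cluster_fraction=0.0,
                         seed=11)
    return generate_scene(params)


@pytest.fixture
def two_channel_field():
    rng = np.random.default_rng(5)
    return FieldImage(
        {"green": rng.integers(0, 60000, (64, 64)).astype(np.uint16),
         "red": rng.integers(0, 60000, (64, 64)).astype(np.uint16)},
        pixel_size_um=0.65)
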