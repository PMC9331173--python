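import numpy as np
import pytest

from vertphen import PlantMask, SyntheticPlantSpec, generate_plant


def paint(mask: np.ndarray, fg=(0, 255, 0), bg=(128, 128, 128)) -> np.ndarray:
    """RGB image with foreground pixels in `fg` colour on a `bg` canvas."""
    img = np.empty(mask.shape + (3,), dtype=np.uint8)
    img[:] = bg
    img[mask.astype(bool)] = fg
    return img


def random_blob_mask(rng: np.random.Generator, shape=(80, 60)) -> PlantMask:
    """Connected random blob: a random walk dilated onto the canvas."""
    h, w = shape
    r, c = h // 2, w // 2
    pix = np.zeros(shape, dtype=bool)
    for _ in range(300):
        pix[max(0, r - 1):r + 2, max(0, c - 1):c + 2] = True
        r = int(np.clip(r + rng.integers(-2, 3), 1, h - 2))
        c = int(np.clip(c + rng.integers(-2, 3), 1, w - 2))
    return PlantMask(pix)


@pytest.fixture(scope="session")
def default_plant():
    """One default synthetic plant, shared across tests (read-only)."""
    return generate_plant(SyntheticPlantSpec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
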