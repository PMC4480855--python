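import numpy as np
import pytest

from neurostereo.simulate import layered_scene
from neurostereo.training import train_codes


@pytest.fixture(scope="session")
def codes200():
    """Activity codes trained at 200 reps/disparity (shared, ~2 s)."""
    return train_codes(n_reps=200, seed=123)


@pytest.fixture(scope="session")
def codes20():
    """Cheap codes for tests that only need a rough decoder."""
    return train_codes(n_reps=20, seed=7)


@pytest.fixture(scope="session")
def scene_one_rect():
    """96x160 layered scene: background at 2, one rectangle at 6."""
    return layered_scene(
        96, 160, [((30, 70, 70, 110), 6, 5)], background_disparity=2, seed=3
    )


def interior_mask(gt: np.ndarray, margin: int = 9) -> np.ndarray:
    """Pixels at least ``margin`` px from any disparity boundary."""
    from scipy.ndimage import binary_erosion

    interior = np.ones(gt.shape, dtype=bool)
    struct = np.ones((2 * margin + 1, 2 * margin + 1))
    for v in np.unique(gt):
        reg = gt == v
        interior &= ~reg | binary_erosion(reg, struct)
    return interior
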