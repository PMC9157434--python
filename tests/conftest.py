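import numpy as np
import pytest

from fpdscore.fixtures import load_confusion
from fpdscore.imaging import PipelineConfig
from fpdscore.synthetic import SyntheticFootSpec, generate_foot


@pytest.fixture(scope="session")
def table3a():
    return load_confusion("table3a")


@pytest.fixture(scope="session")
def table3b():
    return load_confusion("table3b")


@pytest.fixture(scope="session")
def straight_foot():
    """One straight, noise-free foot with a 30% lesion."""
    return generate_foot(SyntheticFootSpec(target_ratio=0.30, seed=7))


@pytest.fixture(scope="session")
def clean_foot():
    """A lesion-free straight foot."""
    return generate_foot(SyntheticFootSpec(target_level=0, seed=7))


@pytest.fixture
def default_pipeline():
    return PipelineConfig()


@pytest.fixture
def blue_image():
    """A uniform background-only frame (empty slaughter hook)."""
    px = np.zeros((128, 128, 3), np.uint8)
    px[:] = (40, 80, 180)
    return px


def random_blob_mask(rng: np.random.Generator, size: int = 64) -> np.ndarray:
    """Union of a few random discs, guaranteed non-trivial."""
    yy, xx = np.mgrid[0:size, 0:size]
    mask = np.zeros((size, size), bool)
    for _ in range(rng.integers(1, 4)):
        cy, cx = rng.uniform(8, size - 8, 2)
        r = rng.uniform(4, size / 3)
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = False
    if not mask.any():
        mask[size // 2, size // 2] = True
    return mask
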