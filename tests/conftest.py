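import numpy as np
import pytest

from evtricoloc.io import ZStack
from evtricoloc.segmentation import build_cell_masks, max_project
from evtricoloc.synthetic import SceneConfig, generate_scene


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_scene():
    """One full-size tri-culture scene at the default study conditions."""
    return generate_scene(SceneConfig(seed=42))


@pytest.fixture(scope="session")
def default_projection(default_scene):
    stack, _ = default_scene
    return max_project(stack)


@pytest.fixture(scope="session")
def default_masks(default_projection):
    return build_cell_masks(default_projection)


@pytest.fixture()
def tiny_stack():
    """A 3-z, 2-channel, 8x8 stack with known values."""
    rng = np.random.default_rng(7)
    pixels = rng.integers(0, 1000, size=(3, 2, 8, 8)).astype(float)
    return ZStack(pixels=pixels, channel_map={"dapi": 0, "cfse": 1})
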