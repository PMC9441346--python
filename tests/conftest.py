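import numpy as np
import pytest

from sadgan.data import RetinalSample
from sadgan.phantom import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom_128():
    """One fixed 128x128 phantom shared across tests."""
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def phantom_64():
    return generate_phantom(PhantomSpec(height=64, width=64, n_trees=2,
                                        branch_depth=3, root_width_px=2.5, seed=7))


@pytest.fixture
def tiny_sample(rng):
    """A small hand-assembled retinal sample (not a phantom)."""
    h = w = 24
    img = rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)
    fov = np.zeros((h, w), dtype=np.uint8)
    fov[2:-2, 2:-2] = 1
    vessels = np.zeros((h, w), dtype=np.uint8)
    vessels[10:14, 4:20] = 1
    vessels &= fov
    return RetinalSample(image=img, vessel_mask=vessels, fov_mask=fov,
                         sample_id="tiny").validate()
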