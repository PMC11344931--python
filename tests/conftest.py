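import numpy as np
import pytest

from nanosip import IonImageStack, SceneConfig
from nanosip.synth import generate_scene


@pytest.fixture
def small_config():
    """A compact scene: 128 px field, three well-separated rods."""
    return SceneConfig(n_cells=3, image_size=128, raster_um=12.0, seed=11)


@pytest.fixture
def small_scene(small_config):
    return generate_scene(small_config, timepoint_h=0.0)


@pytest.fixture
def flat_stack():
    """A featureless six-plane stack of constant counts (no drift, no cells)."""
    counts = np.ones((2, 6, 64, 64), dtype=np.int64)
    return IonImageStack(ion_labels=("12C", "12C14N"), counts=counts, raster_um=6.0)
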