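import numpy as np
import pytest

from alpskit.pipeline import truth_rois
from alpskit.synthetic import PhantomConfig, generate_phantom
from alpskit.tensor import diffusivity_maps


@pytest.fixture
def small_cfg():
    """32^3, 2 mm phantom — big enough that every 5 mm sphere fits its slab."""
    return PhantomConfig(grid_shape=(32, 32, 32), glymph_x=1.35)


@pytest.fixture
def small_phantom(small_cfg):
    return generate_phantom(small_cfg)


def measure_alps(tensors, truth):
    """Noise-free ALPS measurement straight from a tensor field."""
    from alpskit.alps import compute_alps

    return compute_alps(diffusivity_maps(tensors), truth_rois(truth))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
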