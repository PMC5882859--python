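import numpy as np
import pytest

from ivmhisto.seed3d import DetectionParams
from ivmhisto.stacks_io import ChannelRole, ImageStack, MultiChannelStack
from ivmhisto.synth import SynthParams, generate_cell_stack

#: Saturation standardization matched to the sparse (~25-50 cell) probe
#: scenes; the 1.2% default assumes study-density stacks of 150-400 cells.
SPARSE_DETECTION = DetectionParams(saturated_fraction=0.002)


@pytest.fixture(scope="session")
def small_tdtomato_scene():
    """A small bright-channel scene with 25 well-separated cells."""
    params = SynthParams.for_profile(
        "TDTOMATO_like", shape=(40, 128, 128), n_cells=25, rng_seed=7
    )
    return generate_cell_stack(params)


@pytest.fixture(scope="session")
def small_egfp_scene():
    """A small dim-channel scene exercising the rigorous-enhancement path."""
    params = SynthParams.for_profile(
        "EGFP_like", shape=(40, 128, 128), n_cells=25, rng_seed=11
    )
    return generate_cell_stack(params)


@pytest.fixture
def flat_stack():
    """A tiny two-channel stack with simple synthetic content."""
    rng = np.random.default_rng(0)
    a = rng.integers(0, 40, size=(5, 16, 16)).astype(np.uint8)
    b = rng.integers(0, 200, size=(5, 16, 16)).astype(np.uint8)
    return MultiChannelStack(
        {
            ChannelRole.EGFP: ImageStack(a, (1.0, 0.78, 0.78)),
            ChannelRole.TDTOMATO: ImageStack(b, (1.0, 0.78, 0.78)),
        },
        region_id="r0",
        timepoint="D0",
    )
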