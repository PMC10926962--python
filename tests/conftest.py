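import numpy as np
import pytest
from hypothesis import settings

from lcmri import lc_contrast, synthio

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def noiseless_phantom_spec():
    return synthio.PhantomSpec(contrast_ratio=1.15, noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def noiseless_phantom(noiseless_phantom_spec):
    vol, mask, ref_center = synthio.generate_lc_phantom(noiseless_phantom_spec)
    return vol, mask, ref_center


@pytest.fixture(scope="session")
def left_region(noiseless_phantom_spec):
    spec = noiseless_phantom_spec
    side_mask = synthio.rasterize_tube(
        spec.lc_centerlines[0], spec.shape, spec.voxel_size, spec.lc_radius
    )
    return lc_contrast.subdivide_rostrocaudal(side_mask, side="left")


@pytest.fixture
def reference_spec():
    # anterior offset tuned to the 64-voxel default phantom grid (native
    # resolution): the 15x15 region sits in pure pontine background
    return lc_contrast.ReferenceSpec(anterior_offset=25)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
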