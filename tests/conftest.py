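import numpy as np
import pytest

import helaseg as hs


@pytest.fixture(scope="session")
def multi_cell_scene() -> hs.PhantomScene:
    """A small multi-cell phantom frame with a centered ROI crop, shared by
    tests that only read it."""
    spec = hs.PhantomSpec(frame_size=256, n_slices=16, n_cells=3,
                          nucleus_radius_px=(34.0, 5.0), envelope_thickness_px=4,
                          noise_sigma=4.0, seed=11)
    return hs.phantom_roi_and_frame(spec, roi_size=160)


@pytest.fixture(scope="session")
def noise_free_roi():
    """A noise-free single-cell ROI stack with exact ground truth."""
    spec = hs.PhantomSpec(frame_size=256, n_slices=16, n_cells=1,
                          nucleus_radius_px=(50.0, 5.0), envelope_thickness_px=4,
                          noise_sigma=0.0, seed=2)
    vol, lab = hs.generate_phantom(spec)
    return spec, vol, lab


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
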