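import numpy as np
import pytest

from enamel_oct import phantom as ph


@pytest.fixture
def flat_spec():
    """Small noise-free phantom: flat surface at row 50, 200 px enamel."""
    return ph.PhantomSpec(
        shape=(400, 64),
        surface=ph.SurfaceModel(base_row=50),
        enamel_thickness_px=200,
        speckle_k=None,
        noise_floor_sigma=0.0,
    )


@pytest.fixture
def flat_phantom(flat_spec):
    return ph.generate_bscan(flat_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
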