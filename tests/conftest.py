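import numpy as np
import pytest

from gridspect.projector import AcquisitionConfig, Collimator
from gridspect.volume import centered_grid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    """32^3 lattice at the SPECT voxel size."""
    return centered_grid((32, 32, 32), 4.42)


@pytest.fixture
def small_acq():
    """Cheap acquisition: 20 angles, modest sensitivity."""
    return AcquisitionConfig(
        n_projections=20,
        time_per_projection_s=10.0,
        orbit_radius_mm=150.0,
        collimator=Collimator("test", 3.9, 0.0633, 50.0),
    )
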