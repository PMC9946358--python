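import numpy as np
import pytest

from bioink_optics import (
    OpticalProperties,
    SlabGeometry,
    TallyConfig,
    run_forward,
)
from bioink_optics.synthetic_data import PRESETS


@pytest.fixture(scope="session")
def slab_air():
    """1-mm slab in air: the measurement geometry used throughout."""
    return SlabGeometry(thickness=1.0, n_ambient=1.0)


@pytest.fixture(scope="session")
def idx0_props():
    return PRESETS["IDX0"].props


@pytest.fixture(scope="session")
def idx30_props():
    return PRESETS["IDX30"].props


@pytest.fixture(scope="session")
def gaussian_kernel():
    """Discrete 2D Gaussian kernel, sigma = 20 μm on a 5 μm grid, unit sum."""
    pitch, sigma = 5.0, 20.0
    half = int(6 * sigma / pitch)
    xs = (np.arange(2 * half + 1) - half) * pitch
    k1 = np.exp(-(xs**2) / (2 * sigma**2))
    k = np.outer(k1, k1)
    return k / k.sum(), pitch, sigma


@pytest.fixture(scope="session")
def idx_psf_stacks(slab_air, idx0_props, idx30_props):
    """Matched-seed PSF stacks for the two headline conditions (shared by
    several ordering tests; 10^5 photons, slices every 50 μm to 250 μm)."""
    depths = tuple(np.arange(50.0, 251.0, 50.0))
    out = {}
    for name, props in (("IDX0", idx0_props), ("IDX30", idx30_props)):
        cfg = TallyConfig(n_photons=100_000, seed=424, depth_slices=depths)
        out[name] = run_forward(props, slab_air, cfg)
    return out
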