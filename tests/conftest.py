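"""Shared fixtures: small simulated acquisitions reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from spatialsim.datamodel import RawStack
from spatialsim.simulator import (
    NoiseModel,
    default_illumination,
    make_otf3d,
    make_phantom,
    simulate_acquisition,
)

SMALL_SHAPE = (5, 64, 64)
MID_SHAPE = (5, 128, 128)
OPTICS = dict(na=1.2, wavelength_em_nm=525.0, lateral_pixel_nm=62.5, axial_step_nm=125.0)


def make_optics(shape):
    return make_otf3d(
        OPTICS["na"],
        OPTICS["wavelength_em_nm"],
        OPTICS["lateral_pixel_nm"],
        OPTICS["axial_step_nm"],
        shape,
    )


def dense_scatter_volume(shape, n_points=200, baseline=0.05, seed=7):
    """Broadband test object: random bright voxels over a dim baseline."""
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    v = np.zeros(shape)
    pts = rng.integers([0, 8, 8], [nz, ny - 8, nx - 8], size=(n_points, 3))
    v[pts[:, 0], pts[:, 1], pts[:, 2]] = rng.uniform(0.5, 1.0, n_points)
    return v + baseline


@pytest.fixture(scope="session")
def otf_small():
    return make_optics(SMALL_SHAPE)


@pytest.fixture(scope="session")
def params_small(otf_small):
    return default_illumination(otf_small)


@pytest.fixture(scope="session")
def stack_small_clean(otf_small, params_small) -> RawStack:
    """Noise-free acquisition of a point-pair phantom, 64x64x5."""
    phantom = make_phantom("point", SMALL_SHAPE, 150.0, rng_seed=1)
    return simulate_acquisition(phantom, params_small, otf_small, noise=None)


@pytest.fixture(scope="session")
def otf_mid():
    return make_optics(MID_SHAPE)


@pytest.fixture(scope="session")
def params_mid(otf_mid):
    return default_illumination(otf_mid)


@pytest.fixture(scope="session")
def stack_mid_clean(otf_mid, params_mid) -> RawStack:
    """Noise-free acquisition of a dense broadband phantom, 128x128x5."""
    phantom = make_phantom(
        "custom", MID_SHAPE, 0.0, volume=dense_scatter_volume(MID_SHAPE, baseline=0.3)
    )
    return simulate_acquisition(phantom, params_mid, otf_mid, noise=None)


@pytest.fixture(scope="session")
def stack_mid_noisy(otf_mid, params_mid) -> RawStack:
    phantom = make_phantom(
        "custom", MID_SHAPE, 0.0, volume=dense_scatter_volume(MID_SHAPE)
    )
    return simulate_acquisition(
        phantom, params_mid, otf_mid, noise=NoiseModel(500, 2), rng_seed=11
    )


@pytest.fixture(scope="session")
def unmodulated_stack(otf_small) -> RawStack:
    """a1 = a2 = 0: all phase images equal the widefield blur."""
    from spatialsim.datamodel import AngleParams, IlluminationParams

    phantom = make_phantom("point", SMALL_SHAPE, 150.0, rng_seed=1)
    p = 0.8 * otf_small.cutoff_lateral_cpp()
    angles = tuple(
        AngleParams(
            wavevector=(round(p * np.sin(t) * 64) / 64, round(p * np.cos(t) * 64) / 64),
            phase0=0.0,
            a1=0.0,
            a2=0.0,
        )
        for t in np.deg2rad([5.0, 65.0, 125.0])
    )
    params = IlluminationParams(angles=angles)
    return simulate_acquisition(phantom, params, otf_small, noise=None)
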