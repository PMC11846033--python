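"""Simulator: phantoms, 3D OTF properties, and the acquisition forward model."""

import numpy as np
import pytest

from spatialsim._fft import fftn_centered, upsample_lateral
from spatialsim.datamodel import AngleParams, IlluminationParams
from spatialsim.simulator import (
    NoiseModel,
    default_illumination,
    make_otf3d,
    make_phantom,
    simulate_acquisition,
)
from conftest import SMALL_SHAPE, make_optics


class TestMakePhantom:
    def test_point_pairs_record_exact_centers(self):
        ph = make_phantom("point", (41, 512, 512), 150.0, rng_seed=None)
        centers = np.asarray(ph.truth["centers_nm"])
        assert len(centers) > 0 and len(centers) % 2 == 0
        # lateral pairs are exactly 150 nm apart
        lat = centers.reshape(-1, 2, 3)
        seps = np.linalg.norm(lat[:, 1] - lat[:, 0], axis=1)
        assert np.allclose(seps, 150.0)
        assert ph.volume.min() >= 0

    def test_zero_separation_merges_structures(self):
        ph = make_phantom("line", (3, 64, 64), 0.0)
        assert ph.truth["merged"] is True

    def test_sub_voxel_spacing_rejected(self):
        with pytest.raises(ValueError, match="below one voxel"):
            make_phantom("point", (3, 64, 64), 10.0)

    def test_circle_integrated_density_matches_circumference(self):
        # oracle: a thin ring of radius r deposits amplitude * 2*pi*r in total
        radius_px = 12.0
        ph = make_phantom("circle", (3, 64, 64), 2 * radius_px * 62.5, amplitude=2.0)
        expected = 2.0 * 2 * np.pi * radius_px
        assert abs(ph.volume.sum() - expected) / expected < 0.01

    def test_custom_requires_matching_volume(self):
        with pytest.raises(ValueError, match="custom"):
            make_phantom("custom", (3, 64, 64), 0.0)


class TestMakeOtf3d:
    def test_dc_is_one_and_bounded(self):
        otf = make_optics(SMALL_SHAPE)
        nz, ny, nx = otf.otf.shape
        dc = otf.otf[nz // 2, ny // 2, nx // 2]
        assert abs(dc - 1.0) < 1e-6
        assert np.max(np.abs(otf.otf)) <= 1.0 + 1e-6

    def test_zero_beyond_lateral_cutoff(self):
        otf = make_optics((3, 64, 64))
        ky = np.fft.fftshift(np.fft.fftfreq(64, d=62.5))[:, None]
        kx = np.fft.fftshift(np.fft.fftfreq(64, d=62.5))[None, :]
        kr = np.hypot(ky, kx)
        beyond = np.abs(otf.otf[:, kr > otf.cutoff_lateral * 1.02])
        assert beyond.max() < 1e-6

    def test_psf_normalized_nonnegative_transform_pair(self):
        otf = make_optics(SMALL_SHAPE)
        assert otf.psf.min() >= 0
        assert abs(otf.psf.sum() - 1.0) < 1e-5
        back = fftn_centered(np.fft.ifftshift(otf.psf).astype(np.complex128))
        assert np.allclose(back, otf.otf, atol=1e-5)

    def test_focal_plane_fwhm_matches_airy_model(self):
        # oracle: numerical FWHM of the Airy-model profile ~ 0.51 * lambda / NA
        na, wl = 1.2, 525.0
        px = 20.0
        otf = make_otf3d(na, wl, px, 125.0, (1, 256, 256))
        profile = otf.psf[0][128, :].astype(np.float64)
        profile = profile / profile.max()
        above = np.where(profile >= 0.5)[0]
        lo, hi = above[0], above[-1]
        # linear interpolation of the two half-maximum crossings
        left = lo - (profile[lo] - 0.5) / (profile[lo] - profile[lo - 1])
        right = hi + (profile[hi] - 0.5) / (profile[hi] - profile[hi + 1])
        fwhm_nm = (right - left) * px
        expected = 0.51 * wl / na
        assert abs(fwhm_nm - expected) / expected < 0.10

    def test_invalid_na_rejected(self):
        with pytest.raises(ValueError):
            make_otf3d(1.6, 525.0, 62.5, 125.0, SMALL_SHAPE)
        with pytest.raises(ValueError, match="too small"):
            make_otf3d(1.2, 525.0, 62.5, 125.0, (3, 8, 8))


class TestSimulateAcquisition:
    def test_unmodulated_limit_all_images_equal_widefield(self, unmodulated_stack):
        data = unmodulated_stack.data
        ref = data[0, 0]
        for j in range(3):
            for i in range(5):
                assert np.allclose(data[j, i], ref, atol=1e-5 * ref.max())

    def test_phase_average_removes_pattern_for_uniform_phantom(self):
        # the 5-phase mean cancels both sinusoid harmonics exactly, so the
        # phase-averaged image of a uniform object is spatially constant
        # even though the individual phase images carry stripes
        shape = (3, 64, 64)
        otf = make_optics(shape)
        params = default_illumination(otf)
        ph = make_phantom("custom", shape, 0.0, volume=np.ones(shape))
        stack = simulate_acquisition(ph, params, otf, noise=None)
        for j in range(3):
            mean = stack.data[j].mean(axis=0, dtype=np.float64)
            assert mean.std() < 1e-4 * mean.mean()
            assert stack.data[j].std(axis=(1, 2, 3)).max() > 100 * mean.std()

    def test_phase_sum_independent_of_pattern_phase(self):
        # equally spaced steps: the sinusoids integrate out of the 5-phase
        # sum, so shifting the pattern's starting phase leaves it unchanged
        # (smooth positive phantom: the zero clamp never fires)
        import dataclasses
        from scipy.ndimage import gaussian_filter

        shape = (3, 64, 64)
        rng = np.random.default_rng(0)
        v = gaussian_filter(rng.random(shape), (0.8, 2, 2)) + 0.2
        otf = make_optics(shape)
        params = default_illumination(otf)
        shifted = IlluminationParams(
            angles=tuple(
                dataclasses.replace(a, phase0=a.phase0 + 0.83) for a in params.angles
            ),
            phase_steps=params.phase_steps,
        )
        ph = make_phantom("custom", shape, 0.0, volume=v)
        a = simulate_acquisition(ph, params, otf, noise=None)
        b = simulate_acquisition(ph, shifted, otf, noise=None)
        sum_a = a.data.sum(axis=1, dtype=np.float64)
        sum_b = b.data.sum(axis=1, dtype=np.float64)
        assert np.allclose(sum_a, sum_b, rtol=1e-5)

    def test_seeded_determinism(self, otf_small, params_small):
        ph = make_phantom("point", SMALL_SHAPE, 150.0, rng_seed=2)
        a = simulate_acquisition(ph, params_small, otf_small,
                                 noise=NoiseModel(200, 2), rng_seed=5)
        b = simulate_acquisition(ph, params_small, otf_small,
                                 noise=NoiseModel(200, 2), rng_seed=5)
        assert np.array_equal(a.data, b.data)

    def test_background_is_smooth_additive_term(self, otf_small, params_small):
        # smooth positive phantom: the zero clamp never fires, so the
        # background term is recoverable exactly by subtraction
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(2)
        v = gaussian_filter(rng.random(SMALL_SHAPE), (0.8, 2, 2)) + 0.2
        ph = make_phantom("custom", SMALL_SHAPE, 0.0, volume=v)
        clean = simulate_acquisition(ph, params_small, otf_small, noise=None)
        with_bg = simulate_acquisition(ph, params_small, otf_small,
                                       background_strength=2.0, noise=None)
        diff = with_bg.data.astype(np.float64) - clean.data.astype(np.float64)
        # additive: identical across angles and phases
        assert np.allclose(diff, diff[0, 0][None, None], atol=1e-4 * diff.max())
        # smooth: energy concentrated at low lateral frequency
        spec = np.abs(fftn_centered(diff[0, 0].astype(np.complex128)))
        ny = spec.shape[1]
        lowpass = spec[:, ny // 2 - 8 : ny // 2 + 8, ny // 2 - 8 : ny // 2 + 8]
        assert lowpass.sum() > 0.95 * spec.sum()

    def test_first_order_band_peaks_at_pattern_frequency(self, otf_small):
        # uniform phantom: the first-order band is a pure carrier, so its
        # spectrum peaks exactly at +p (brute-force argmax oracle)
        shape = SMALL_SHAPE
        ph = make_phantom("custom", shape, 0.0, volume=np.ones(shape))
        params = default_illumination(otf_small)
        stack = simulate_acquisition(ph, params, otf_small, noise=None)
        from spatialsim.params import separate_bands, BAND_ORDERS

        for j, ang in enumerate(params.angles):
            bands = separate_bands(stack, j, params.phase_steps)
            b1 = bands[BAND_ORDERS.index(1)][2]
            spec = np.abs(np.fft.fftshift(np.fft.fft2(b1)))
            iy, ix = np.unravel_index(np.argmax(spec), spec.shape)
            f = np.fft.fftshift(np.fft.fftfreq(64))
            assert abs(f[iy] - ang.wavevector[0]) <= 0.5 / 64
            assert abs(f[ix] - ang.wavevector[1]) <= 0.5 / 64

    def test_nonpositive_photon_budget_rejected(self):
        with pytest.raises(ValueError, match="photon_budget"):
            NoiseModel(photon_budget=0.0)
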