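"""Frequency optimization: notch, apodization, two-step denoise, pipeline."""

import numpy as np
import pytest

from spatialsim._fft import fftn_centered, ifftn_centered, lateral_freq_grids
from spatialsim.datamodel import FilterBank, SRVolume
from spatialsim.freqopt import (
    apodize,
    effective_transfer,
    notch_filter,
    optimize,
    two_step_denoise,
)
from spatialsim.spatial import recombine_spatial


@pytest.fixture(scope="module")
def flat_spectrum():
    return np.ones((3, 64, 64), dtype=np.complex128)


class TestNotchFilter:
    def test_zero_depth_is_identity(self, flat_spectrum, params_small):
        out = notch_filter(flat_spectrum, params_small, 0.01, 0.0)
        assert out is flat_spectrum

    def test_spike_at_peak_strongly_attenuated(self, params_small):
        spec = np.zeros((1, 128, 128), dtype=np.complex128)
        p = params_small.angles[0].wavevector
        ky, kx = lateral_freq_grids(128, 128, 2)
        iy = int(np.argmin(np.abs(ky[:, 0] - p[0])))
        ix = int(np.argmin(np.abs(kx[0, :] - p[1])))
        spec[0, iy, ix] = 1.0
        out = notch_filter(spec, params_small, 0.01, 1.0, upsample=2)
        assert np.abs(out[0, iy, ix]) < 0.01

    def test_energy_far_from_peaks_preserved(self, params_small):
        rng = np.random.default_rng(0)
        spec = rng.normal(size=(1, 128, 128)) + 0j
        width = 0.01
        out = notch_filter(spec, params_small, width, 0.95, upsample=2)
        ky, kx = lateral_freq_grids(128, 128, 2)
        far = np.ones((128, 128), dtype=bool)
        for ang in params_small.angles:
            for m in (-2, -1, 1, 2):
                d = np.hypot(ky - m * ang.wavevector[0], kx - m * ang.wavevector[1])
                far &= d > 5 * width
        before = np.sum(np.abs(spec[0][far]) ** 2)
        after = np.sum(np.abs(out[0][far]) ** 2)
        assert abs(after - before) / before < 1e-3

    def test_depth_out_of_range_rejected(self, flat_spectrum, params_small):
        with pytest.raises(ValueError):
            notch_filter(flat_spectrum, params_small, 0.01, 1.5)


class TestApodize:
    def test_constant_spectrum_returns_window(self, flat_spectrum):
        out = apodize(flat_spectrum, 0.5, upsample=2)
        ky, kx = lateral_freq_grids(64, 64, 2)
        kr = np.hypot(ky, kx)
        expected = np.clip(1 - kr / 0.5, 0, 1)
        assert np.allclose(out[0].real, expected)

    def test_support_beyond_cutoff_is_zero(self, flat_spectrum):
        out = apodize(flat_spectrum, 0.3, upsample=2)
        ky, kx = lateral_freq_grids(64, 64, 2)
        kr = np.hypot(ky, kx)
        assert np.abs(out[0][kr >= 0.3]).max() == 0.0

    def test_apodized_delta_has_small_sidelobes(self):
        spec = np.ones((1, 256, 256), dtype=np.complex128)
        out = apodize(spec, 0.25, upsample=1)
        img = np.abs(ifftn_centered(out[0]))
        img = np.fft.fftshift(img)
        center = img[128, 128]
        profile = img[128, 129:]
        # first minimum then the largest later bump is the sidelobe
        first_min = int(np.argmin(profile[:30]))
        sidelobe = profile[first_min:].max()
        assert sidelobe < 0.05 * center


class TestTwoStepDenoise:
    def test_large_w_asymptote_is_matched_filter(self, flat_spectrum):
        h = np.full(flat_spectrum.shape, 0.5)
        w = 1e6
        out = two_step_denoise(flat_spectrum, h, w)
        assert np.allclose(out, flat_spectrum * 0.5 / (0.25 + w), rtol=1e-6)

    def test_out_of_band_noise_removed(self):
        rng = np.random.default_rng(1)
        spec = rng.normal(size=(1, 64, 64)) + 0j
        mask = np.zeros((1, 64, 64), dtype=bool)
        mask[:, 16:48, 16:48] = True
        noise_only = np.where(mask, 0.0, spec)
        out = two_step_denoise(noise_only, np.ones_like(spec.real), 0.1,
                               support_mask=mask, suppression=1.0)
        assert np.sum(np.abs(out) ** 2) < 0.01 * np.sum(np.abs(noise_only) ** 2)

    def test_monotone_in_w(self, flat_spectrum):
        rng = np.random.default_rng(2)
        h = rng.uniform(0.01, 1.0, size=flat_spectrum.shape)
        prev = None
        for w in (0.01, 0.1, 1.0, 10.0):
            out = np.abs(two_step_denoise(flat_spectrum, h, w))
            if prev is not None:
                assert (out <= prev + 1e-12).all()
            prev = out

    def test_nonpositive_w_rejected(self, flat_spectrum):
        with pytest.raises(ValueError):
            two_step_denoise(flat_spectrum, np.ones_like(flat_spectrum.real), 0.0)


class TestOptimize:
    def test_identity_configuration_reproduces_input(
        self, stack_small_clean, params_small, otf_small
    ):
        sr0 = recombine_spatial(stack_small_clean, params_small)
        sr1 = optimize(sr0, params_small, otf_small, FilterBank.identity())
        assert sr1.stage == "SR1"
        assert np.allclose(sr1.data, sr0.data, atol=1e-9 * np.abs(sr0.data).max())

    def test_output_is_real_and_finite(self, stack_small_clean, params_small, otf_small):
        sr0 = recombine_spatial(stack_small_clean, params_small)
        sr1 = optimize(sr0, params_small, otf_small, FilterBank())
        assert np.isrealobj(sr1.data) and np.isfinite(sr1.data).all()

    def test_wrong_stage_rejected(self, params_small, otf_small):
        vol = SRVolume(np.zeros((2, 64, 64)), "SR1", 31.25, 125.0)
        with pytest.raises(ValueError, match="SR0_minus"):
            optimize(vol, params_small, otf_small, FilterBank())

    def test_three_layer_stack_interior_plane_close_to_deep_stack(
        self, stack_small_clean, params_small, otf_small
    ):
        import dataclasses
        from spatialsim.simulator import make_otf3d

        sr0_full = recombine_spatial(stack_small_clean, params_small)
        sr1_full = optimize(sr0_full, params_small, otf_small, FilterBank())
        sub = dataclasses.replace(
            stack_small_clean,
            data=np.ascontiguousarray(stack_small_clean.data[:, :, 1:4]),
        )
        otf3 = make_otf3d(1.2, 525.0, 62.5, 125.0, (3, 64, 64))
        sr1_sub = optimize(
            recombine_spatial(sub, params_small), params_small, otf3, FilterBank()
        )
        mid_full = sr1_full.data[2]
        mid_sub = sr1_sub.data[1]
        rel = np.linalg.norm(mid_sub - mid_full) / np.linalg.norm(mid_full)
        assert rel < 0.35  # interior plane, limited-layer path stays faithful


def test_effective_transfer_normalized_and_positive(params_small, otf_small):
    t = effective_transfer(params_small, otf_small, (5, 128, 128))
    assert t.shape == (5, 128, 128)
    assert t.min() >= 0 and abs(t.max() - 1.0) < 1e-6
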