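"""Spatial-domain recombination: zero-order removal, demixing, carrier sums."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spatialsim.datamodel import DEFAULT_PHASE_STEPS
from spatialsim.spatial import (
    build_demix_matrix,
    coefficient_field,
    recombine_spatial,
    remove_zero_order,
)
from conftest import SMALL_SHAPE


class TestRemoveZeroOrder:
    def test_unmodulated_stack_becomes_zero(self, unmodulated_stack):
        out = remove_zero_order(unmodulated_stack, angle=0)
        assert np.abs(out).max() < 1e-4 * unmodulated_stack.data.max()

    def test_phase_mean_zero_to_machine_precision(self, stack_mid_noisy):
        out = remove_zero_order(stack_mid_noisy, angle=1)
        assert np.abs(out.sum(axis=0)).max() < 1e-9 * stack_mid_noisy.data.max()

    def test_phase_independent_background_cancels_exactly(self, stack_small_clean):
        rng = np.random.default_rng(0)
        bg = rng.random(stack_small_clean.data.shape[2:]) * 50.0
        polluted = dataclasses.replace(
            stack_small_clean,
            data=stack_small_clean.data + bg[None, None].astype(np.float32),
        )
        a = remove_zero_order(stack_small_clean, angle=0)
        b = remove_zero_order(polluted, angle=0)
        assert np.abs(a - b).max() < 1e-10 * bg.max() + 1e-4


class TestBuildDemixMatrix:
    def test_equal_steps_give_orthogonality_weights(self):
        # oracle: brute-force pseudoinverse of the full trigonometric design
        phi = np.asarray(DEFAULT_PHASE_STEPS)
        m = build_demix_matrix(phi)
        assert np.allclose(m[0], (2 / 5) * np.cos(phi), atol=1e-12)
        assert np.allclose(m[1], (2 / 5) * np.sin(phi), atol=1e-12)
        assert np.allclose(m[2], (2 / 5) * np.cos(2 * phi), atol=1e-12)
        assert np.allclose(m[3], (2 / 5) * np.sin(2 * phi), atol=1e-12)

    def test_duplicate_steps_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            build_demix_matrix([0.0, 0.0, 1.0, 2.0, 3.0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-0.3, max_value=0.3, allow_nan=False),
            min_size=5,
            max_size=5,
        )
    )
    def test_perturbed_steps_stay_solvable_and_dc_orthogonal(self, jitter):
        phi = np.asarray(DEFAULT_PHASE_STEPS) + np.asarray(jitter)
        m = build_demix_matrix(phi)
        # weights recover the harmonics they target exactly (residual ~ 0)
        design = np.column_stack(
            [np.cos(phi), np.sin(phi), np.cos(2 * phi), np.sin(2 * phi)]
        )
        assert np.allclose(m @ design, np.eye(4), atol=1e-9)
        # and are orthogonal to the (already removed) DC component
        assert np.allclose(m.sum(axis=1), 0.0, atol=1e-9)


class TestRecombineSpatial:
    def test_unmodulated_stack_recombines_to_zero(self, unmodulated_stack, params_small):
        sr0 = recombine_spatial(unmodulated_stack, params_small)
        assert np.abs(sr0.data).max() < 1e-3 * unmodulated_stack.data.max()

    def test_linearity(self, stack_small_clean, params_small):
        doubled = dataclasses.replace(
            stack_small_clean, data=2.0 * stack_small_clean.data
        )
        a = recombine_spatial(stack_small_clean, params_small)
        b = recombine_spatial(doubled, params_small)
        assert np.allclose(b.data, 2.0 * a.data, atol=1e-6 * np.abs(a.data).max())

    def test_coefficients_sum_to_zero_per_pixel(self, params_small):
        demix = build_demix_matrix(params_small.phase_steps)
        c = coefficient_field(params_small.angles[0], demix, (32, 32))
        assert np.abs(c.sum(axis=0)).max() < 1e-12

    def test_spectrum_has_lobes_at_harmonic_positions(self, otf_small, params_small):
        # single point: |FFT(SR0_minus)| concentrates around +-p, +-2p
        from spatialsim.simulator import make_phantom, simulate_acquisition
        from spatialsim._fft import fftn_centered, freq_axis

        v = np.zeros(SMALL_SHAPE)
        v[2, 32, 32] = 1.0
        ph = make_phantom("custom", SMALL_SHAPE, 0.0, volume=v)
        stack = simulate_acquisition(ph, params_small, otf_small, noise=None)
        sr0 = recombine_spatial(stack, params_small)
        spec = np.abs(fftn_centered(sr0.data.astype(np.complex128))).sum(axis=0)
        f = freq_axis(128, d=0.5)
        ky, kx = np.meshgrid(f, f, indexing="ij")
        total = spec.sum()
        near_harmonic = np.zeros_like(spec, dtype=bool)
        cutoff = otf_small.cutoff_lateral_cpp()
        for ang in params_small.angles:
            for m in (-2, -1, 1, 2):
                d = np.hypot(ky - m * ang.wavevector[0], kx - m * ang.wavevector[1])
                near_harmonic |= d <= cutoff
        assert spec[near_harmonic].sum() > 0.98 * total

    def test_single_plane_stack_supported(self, otf_small, params_small):
        from spatialsim.simulator import make_phantom, simulate_acquisition

        v = np.zeros((1, 64, 64))
        v[0, 30, 34] = 1.0
        ph = make_phantom("custom", (1, 64, 64), 0.0, volume=v)
        from spatialsim.simulator import make_otf3d

        otf1 = make_otf3d(1.2, 525.0, 62.5, 125.0, (1, 64, 64))
        stack = simulate_acquisition(ph, params_small, otf1, noise=None)
        sr0 = recombine_spatial(stack, params_small)
        assert sr0.data.shape == (1, 128, 128)
        assert np.isfinite(sr0.data).all()

    def test_limited_layer_planes_equal_deep_stack_planes(
        self, stack_small_clean, params_small
    ):
        # recombination is purely per-plane: a 2-layer sub-stack reconstructs
        # to exactly the corresponding planes of the full stack
        full = recombine_spatial(stack_small_clean, params_small)
        sub = dataclasses.replace(
            stack_small_clean,
            data=np.ascontiguousarray(stack_small_clean.data[:, :, 1:3]),
        )
        part = recombine_spatial(sub, params_small)
        assert np.array_equal(part.data, full.data[1:3])
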