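"""Illumination-parameter estimation by cross-correlation (COR).

The pattern wavevector, starting phase and modulation depths are estimated
once per dataset and then treated as prior knowledge by the reconstruction
stages.  The wavevector comes from the correlation between the first-order
and zero-order harmonic images, refined to sub-pixel precision by a
shrinking grid search of the correlation DTFT magnitude.  The starting
phase and modulation depths come from a least-squares fit of each
carrier-demodulated band against the zero-order band over the
OTF-supported overlap region, with a noise-floor correction that debiases
the fit at low photon counts.
"""

from __future__ import annotations

import numpy as np

from ._fft import carrier_phase, crop_centered_lateral, fftn_centered, freq_axis
from .datamodel import (
    AngleParams,
    IlluminationParams,
    OTFModel,
    RawStack,
    N_ANGLES,
    N_PHASES,
)

#: harmonic order of each band row returned by `separate_bands`
BAND_ORDERS = (-2, -1, 0, 1, 2)


class PatternNotDetectedError(ValueError):
    """No significant illumination-pattern peak found in the data."""


def separate_bands(
    stack: RawStack | np.ndarray, angle: int, phase_steps=None
) -> np.ndarray:
    """Separate one angle's 5 phase images into harmonic bands m = -2..+2.

    Inverts the 5x5 phase-mixing matrix E with entries exp(j*m*phi_i) per
    pixel.  Returns a complex array of shape ``(5, z, y, x)`` ordered as
    ``BAND_ORDERS``; the m=0 row is the widefield image.

    Raises
    ------
    ValueError
        if the phase steps make E singular (e.g. duplicate steps).
    """
    if isinstance(stack, RawStack):
        data = stack.data[angle]
        if phase_steps is None:
            phase_steps = np.asarray([2 * np.pi * i / N_PHASES for i in range(N_PHASES)])
    else:
        data = np.asarray(stack)
        if data.ndim == 5:
            data = data[angle]
        if phase_steps is None:
            raise ValueError("phase_steps required when passing a bare array")
    phi = np.asarray(phase_steps, dtype=np.float64)
    orders = np.asarray(BAND_ORDERS)
    mix = np.exp(1j * phi[:, None] * orders[None, :])  # (phase, m)
    cond = np.linalg.cond(mix)
    if not np.isfinite(cond) or cond > 1e9:
        raise ValueError(
            f"phase-separation matrix is singular (cond={cond:.3g}); "
            "check for duplicate phase steps"
        )
    demix = np.linalg.inv(mix)  # (m, phase)
    cdtype = np.complex64 if data.size > 20_000_000 else np.complex128
    return np.tensordot(demix.astype(cdtype), data.astype(cdtype), axes=([1], [0]))


def _band(bands: np.ndarray, m: int) -> np.ndarray:
    return bands[BAND_ORDERS.index(m)]


def estimate_wavevector(
    stack: RawStack,
    angle: int,
    *,
    phase_steps=None,
    min_freq: float | None = None,
    score_threshold: float = 8.0,
) -> tuple[tuple[float, float], float]:
    """Estimate the pattern wavevector (ky, kx) in cycles/pixel for one angle.

    Cross-correlates the m=+1 band against the m=0 band: the pixelwise
    product ``C = B1 * conj(B0)`` is a plane-wave phasor at the pattern
    frequency.  Its 2D spectrum (pooled over z) gives the integer-bin peak,
    refined to sub-pixel precision by a shrinking grid search of the
    correlation DTFT magnitude.  Returns ``((ky, kx), score)`` where
    ``score`` is the peak-to-median spectral magnitude ratio.

    ``min_freq`` excludes a low-frequency disk from the peak search where
    residual object correlation leaks (detector clamping and other mild
    nonlinearities); the default is 0.35x the detection cutoff — SIM
    patterns sit near the pupil edge, far above it.

    Raises
    ------
    PatternNotDetectedError
        if the correlation peak is below ``score_threshold`` (e.g. a1 = 0).
    """
    if min_freq is None:
        cutoff_cpp = (
            2.0 * stack.na / stack.wavelength_em_nm * stack.lateral_pixel_nm
        )
        min_freq = 0.35 * cutoff_cpp
    bands = separate_bands(stack, angle, phase_steps)
    b1, b0 = _band(bands, +1), _band(bands, 0)
    # absolute modulation check: with a1 = 0 the first-order band is only
    # arithmetic residue of the separation, however structured it looks
    e1 = float(np.linalg.norm(b1.ravel()))
    e0 = float(np.linalg.norm(b0.ravel()))
    if e0 <= 0 or e1 < 1e-3 * e0:
        raise PatternNotDetectedError(
            f"angle {angle}: first-order band energy is {e1 / max(e0, 1e-300):.2e} "
            "of the zero order; pattern not detected"
        )
    # pool z planes for SNR before correlating
    corr = (b1 * np.conj(b0)).sum(axis=0)
    ny, nx = corr.shape
    spec = np.fft.fftshift(np.fft.fft2(corr))
    ky = freq_axis(ny)[:, None]
    kx = freq_axis(nx)[None, :]
    valid = (ky * ky + kx * kx) >= min_freq * min_freq
    mag = np.abs(spec)
    med = np.median(mag[valid]) if valid.any() else 0.0
    mag_masked = np.where(valid, mag, 0.0)
    iy, ix = np.unravel_index(np.argmax(mag_masked), mag.shape)
    peak = mag_masked[iy, ix]
    score = float(peak / med) if med > 0 else 0.0
    if not np.isfinite(score) or score < score_threshold:
        raise PatternNotDetectedError(
            f"angle {angle}: pattern not detected (score {score:.2f} < "
            f"threshold {score_threshold})"
        )
    q0y, q0x = float(ky[iy, 0]), float(kx[0, ix])

    # sub-pixel refinement: shrinking grid search of the correlation DTFT
    # magnitude around the coarse bin (deterministic, no tuning grid)
    qy, qx = q0y, q0x
    bin_y, bin_x = 1.0 / ny, 1.0 / nx
    for half, n_pts in ((1.0, 9), (0.25, 11), (0.05, 11), (0.01, 11)):
        qy, qx = _dtft_argmax(
            corr,
            qy + np.linspace(-half, half, n_pts) * bin_y,
            qx + np.linspace(-half, half, n_pts) * bin_x,
        )
    return (qy, qx), score


def _dtft_argmax(field: np.ndarray, qy_list: np.ndarray, qx_list: np.ndarray):
    """(qy, qx) maximizing |sum_r field(r) e^{-2pi i q.r}| over the grid."""
    ny, nx = field.shape
    ey = np.exp(-2j * np.pi * np.outer(qy_list, np.arange(ny)))
    ex = np.exp(-2j * np.pi * np.outer(qx_list, np.arange(nx)))
    mags = np.abs(ey @ field @ ex.T)
    iy, ix = np.unravel_index(np.argmax(mags), mags.shape)
    return float(qy_list[iy]), float(qx_list[ix])


def estimate_phase_and_depths(
    stack: RawStack,
    angle: int,
    wavevector: tuple[float, float],
    *,
    otf: OTFModel | None = None,
    phase_steps=None,
    support_threshold: float = 0.02,
) -> tuple[float, float, float]:
    """Estimate (phase0, a1, a2) for one angle given its wavevector.

    Each order-m band is first demodulated by its own carrier,
    ``X_m = FFT[B_m(r) * exp(-2*pi*i*m*p.r)]``, which brings the band's
    off-grid frequency comb exactly onto the sampling grid, so that
    ``X_m(k) = (a_m/2) * exp(i*m*phase0) * V(k) * OTF(k + m*p)`` holds
    bin-by-bin (the opposite ordering — shifting the on-grid zero band off
    grid — suffers Dirichlet leakage on broadband objects).  The object
    spectrum ``V`` is read off the zero-order band over the OTF-supported
    overlap region and the complex scale is solved by least squares.

    Raises
    ------
    ValueError
        if the OTF-supported overlap region is empty.
    """
    from .simulator import make_otf3d  # deferred: simulator imports datamodel only

    bands = separate_bands(stack, angle, phase_steps)
    nz, ny, nx = bands.shape[1:]
    if otf is None:
        otf = make_otf3d(
            stack.na,
            stack.wavelength_em_nm,
            stack.lateral_pixel_nm,
            stack.axial_step_nm,
            (nz, ny, nx),
        )
    otf0 = np.abs(otf.otf)
    w0 = fftn_centered(_band(bands, 0))
    # spectral noise floor of the zero band, from far out-of-band bins;
    # used to debias the least-squares scale (the regressor is built from
    # the noisy zero band, which otherwise attenuates the estimate)
    noise_bins = otf0 < 1e-3
    noise_var = float(np.mean(np.abs(w0[noise_bins]) ** 2)) if noise_bins.any() else 0.0
    # The displaced OTF is sampled on a 2x fine grid and cropped: the
    # second-harmonic displacement 2|p| can exceed the raw Nyquist
    # frequency, where a raw-grid evaluation would alias.
    otf_fine = make_otf3d(
        otf.na,
        otf.wavelength_em_nm,
        otf.lateral_pixel_nm / 2.0,
        otf.axial_step_nm,
        (nz, 2 * ny, 2 * nx),
    )
    psf_fine_nat = np.fft.ifftshift(otf_fine.psf)

    cdtype = np.complex64 if bands[0].size > 4_000_000 else np.complex128

    def order_scale(m: int) -> complex:
        p = (m * wavevector[0], m * wavevector[1])
        # carrier demodulation in real space: exact for off-grid p
        ramp = np.exp(-1j * carrier_phase(ny, nx, p, 0.0)).astype(cdtype)[None, :, :]
        x_m = fftn_centered(_band(bands, m).astype(cdtype) * ramp)
        # OTF displaced by +m*p, sampled via the same ramp trick on the
        # fine grid and cropped to the raw bins
        ramp_f = np.exp(
            -1j * carrier_phase(2 * ny, 2 * nx, p, 0.0, upsample=2)
        ).astype(cdtype)[None, :, :]
        otf_s = crop_centered_lateral(
            np.abs(fftn_centered(psf_fine_nat * ramp_f)), ny
        )
        overlap = (otf0 > support_threshold) & (otf_s > support_threshold)
        if not overlap.any():
            raise ValueError(
                f"angle {angle}, order {m}: OTF overlap region is empty "
                f"(|p| too large for the detection cutoff?)"
            )
        # model: object spectrum from the zero band times the displaced OTF
        gain = otf_s[overlap] / otf0[overlap]
        model = w0[overlap] * gain
        num = np.vdot(model, x_m[overlap])
        den = np.vdot(model, model).real
        # errors-in-variables correction: subtract the noise power that the
        # zero band contributes to the regressor's norm
        den_corr = den - noise_var * float(np.sum(gain * gain))
        if den_corr < 0.25 * den:  # guard against overshoot at very low SNR
            den_corr = 0.25 * den
        return num / den_corr

    # (the -m bands of real-valued data are exact conjugates of the +m
    # bands and carry no independent information)
    c1 = order_scale(+1)
    c2 = order_scale(+2)
    phase0 = float(np.angle(c1))
    a1 = float(np.clip(2 * np.abs(c1), 0.0, 1.0))
    a2 = float(np.clip(2 * np.abs(c2), 0.0, a1))
    return phase0, a1, a2


def estimate_illumination(
    stack: RawStack,
    *,
    phase_steps=None,
    otf: OTFModel | None = None,
    score_threshold: float = 8.0,
    max_z_planes: int = 9,
) -> IlluminationParams:
    """Estimate all three angles' illumination parameters from a raw stack.

    The illumination parameters do not depend on z, so deep stacks are
    estimated from their ``max_z_planes`` central planes (SNR pooling with
    bounded memory).
    """
    stack.validate()
    nz = stack.n_z
    if nz > max_z_planes:
        z0 = (nz - max_z_planes) // 2
        import dataclasses

        stack = dataclasses.replace(
            stack, data=stack.data[:, :, z0 : z0 + max_z_planes]
        )
    steps = (
        tuple(phase_steps)
        if phase_steps is not None
        else tuple(2 * np.pi * i / N_PHASES for i in range(N_PHASES))
    )
    angles = []
    for j in range(N_ANGLES):
        p, _score = estimate_wavevector(
            stack, j, phase_steps=steps, score_threshold=score_threshold
        )
        phase0, a1, a2 = estimate_phase_and_depths(
            stack, j, p, otf=otf, phase_steps=steps
        )
        angles.append(AngleParams(wavevector=p, phase0=phase0, a1=a1, a2=a2))
    return IlluminationParams(angles=tuple(angles), phase_steps=steps)
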