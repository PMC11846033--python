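"""Spatial-domain SIM recombination with the zero order removed.

The super-resolved volume is built as a per-pixel weighted sum of the raw
phase images,

    SR0_minus(r, z) = sum_theta sum_i c_theta,i(r) * D'_theta,i(r, z),

where ``D'`` are the phase images after subtraction of their per-pixel mean
over the five phases (the unmodulated zero order, which carries the
defocused background) and the coefficients ``c`` are carrier phasors
cos/sin(psi) and cos/sin(2*psi) evaluated analytically on the 2x output
grid, mixed by the inverse of the trigonometric phase-step design.  This
plants the +-1 and +-2 harmonics at their true frequency positions without
any explicit spectrum separation or shifting.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as sfft

from ._fft import carrier_phase, pad_centered_lateral
from .datamodel import (
    IlluminationParams,
    AngleParams,
    RawStack,
    SRVolume,
    N_ANGLES,
    N_PHASES,
)

#: modulation depths are floored here before dividing, Wiener-style gain limiting
A_FLOOR = 0.05


def remove_zero_order(stack: RawStack | np.ndarray, angle: int | None = None) -> np.ndarray:
    """Subtract the per-pixel mean over the 5 phases (the zero order).

    Any phase-independent additive term — in particular a defocused
    background — cancels exactly.  Returns float64 with zero phase-mean at
    every pixel; shape ``(5, z, y, x)`` for a single ``angle`` or
    ``(3, 5, z, y, x)`` when ``angle`` is None.
    """
    data = stack.data if isinstance(stack, RawStack) else np.asarray(stack)
    data = data.astype(np.float64, copy=False)
    if angle is not None:
        data = data[angle]
        return data - data.mean(axis=0, keepdims=True)
    return data - data.mean(axis=1, keepdims=True)


def build_demix_matrix(phase_steps) -> np.ndarray:
    """Operator mapping the 5 zero-mean phase images to the 4 harmonic
    basis amplitudes {cos psi, sin psi, cos 2psi, sin 2psi}.

    Solves the full 5x5 trigonometric design ``[1, cos phi_i, sin phi_i,
    cos 2phi_i, sin 2phi_i]`` and returns its non-DC rows (4 x 5); treating
    the (already subtracted) DC as an explicit nuisance makes every returned
    weight row sum exactly to zero.  For equally spaced steps this is the
    classic orthogonality result: the cos-psi weights are (2/5)cos(phi_i).

    Raises
    ------
    ValueError
        if the steps make the design rank-deficient (e.g. duplicate steps).
    """
    phi = np.asarray(phase_steps, dtype=np.float64)
    if phi.shape != (N_PHASES,):
        raise ValueError(f"need {N_PHASES} phase steps; got shape {phi.shape}")
    design = np.column_stack(
        [np.ones_like(phi), np.cos(phi), np.sin(phi), np.cos(2 * phi), np.sin(2 * phi)]
    )
    if np.linalg.matrix_rank(design, tol=1e-9) < 5:
        raise ValueError(
            "phase-step design is singular (duplicate or degenerate steps); "
            f"steps={np.round(phi, 6).tolist()}"
        )
    return np.linalg.inv(design)[1:, :]


def coefficient_field(
    ang: AngleParams,
    demix: np.ndarray,
    shape_yx: tuple[int, int],
    upsample: int = 2,
    a_floor: float = A_FLOOR,
) -> np.ndarray:
    """Per-phase recombination coefficients c_i(r) on the fine grid.

    ``shape_yx`` is the *raw* lateral shape; the returned field has shape
    ``(5, upsample*ny, upsample*nx)``.  First/second-harmonic contributions
    are divided by the (floored) modulation depths a1, a2.  At every pixel
    ``sum_i c_i = 0`` — the coefficients are orthogonal to the removed
    zero order.
    """
    ny, nx = shape_yx
    psi = carrier_phase(upsample * ny, upsample * nx, ang.wavevector, ang.phase0, upsample)
    g1 = 1.0 / max(ang.a1, a_floor)
    g2 = 1.0 / max(ang.a2, a_floor)
    cos1, sin1 = np.cos(psi), np.sin(psi)
    cos2, sin2 = np.cos(2 * psi), np.sin(2 * psi)
    out = np.empty((N_PHASES,) + cos1.shape, dtype=np.float64)
    for i in range(N_PHASES):
        out[i] = g1 * (cos1 * demix[0, i] - sin1 * demix[1, i]) + g2 * (
            cos2 * demix[2, i] - sin2 * demix[3, i]
        )
    return out


def _upsample_plane(plane: np.ndarray, upsample: int) -> np.ndarray:
    """2D band-limited upsampling of one real z plane (see _fft helpers)."""
    spec = np.fft.fftshift(sfft.fft2(plane))
    spec = pad_centered_lateral(spec, upsample)
    return sfft.ifft2(np.fft.ifftshift(spec)).real * (upsample * upsample)


def recombine_spatial(
    stack: RawStack,
    params: IlluminationParams,
    *,
    upsample: int = 2,
    a_floor: float = A_FLOOR,
) -> SRVolume:
    """Spatial-domain recombination of a raw stack into the SR0_minus volume.

    The zero order is removed internally per angle; each zero-mean phase
    image is Fourier-upsampled 2x laterally and summed with the analytic
    coefficient field.  Purely per-plane laterally — no cross-plane
    coupling, so limited-layer stacks (even a single z plane) reconstruct
    identically to the same planes of a deeper stack.
    """
    stack.validate()
    if len(params.angles) != N_ANGLES:
        raise ValueError(f"params must provide {N_ANGLES} angles")
    nz, ny, nx = stack.data.shape[2:]
    demix = build_demix_matrix(params.phase_steps)
    big = nz * ny * nx * upsample * upsample > 20_000_000
    out = np.zeros((nz, upsample * ny, upsample * nx),
                   dtype=np.float32 if big else np.float64)
    for j, ang in enumerate(params.angles):
        zero_mean = remove_zero_order(stack, angle=j)
        coeff = coefficient_field(ang, demix, (ny, nx), upsample, a_floor)
        for z in range(nz):
            for i in range(N_PHASES):
                out[z] += coeff[i] * _upsample_plane(zero_mean[i, z], upsample)
    return SRVolume(
        data=out,
        stage="SR0_minus",
        lateral_pixel_nm=stack.lateral_pixel_nm / upsample,
        axial_step_nm=stack.axial_step_nm,
    )
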