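"""Classical frequency-domain 3D-SIM reconstruction (the correctness oracle).

Per angle the five phase images are separated into harmonic bands with the
phase matrix, each band is Fourier-upsampled to the 2x lateral grid,
shifted back to its true frequency position (an exact sub-pixel shift via a
real-space phase ramp) and the bands are merged — either by a generalized
Wiener combination (the traditional reconstruction) or by a plain
1/a-weighted band sum that mirrors the spatial recombination exactly and
serves as the cross-implementation equivalence target.
"""

from __future__ import annotations

import numpy as np

from ._fft import carrier_phase, fftn_centered, ifftn_centered, upsample_lateral
from .datamodel import (
    FilterBank,
    IlluminationParams,
    OTFModel,
    RawStack,
    SRVolume,
    N_ANGLES,
)
from .params import separate_bands, BAND_ORDERS
from .spatial import A_FLOOR


def shift_band(band_spectrum: np.ndarray, shift_bins: tuple[float, float]) -> np.ndarray:
    """Shift a DC-centered spectrum laterally by (by, bx) frequency bins.

    Implemented as multiplication by a linear phase ramp in real space, so
    fractional (sub-pixel) shifts are exact; an integer shift equals a
    circular roll of the spectrum.  The last two axes are the lateral ones.
    """
    by, bx = shift_bins
    ny, nx = band_spectrum.shape[-2], band_spectrum.shape[-1]
    x = ifftn_centered(band_spectrum, axes=(-2, -1))
    yy = np.arange(ny).reshape((ny, 1))
    xx = np.arange(nx).reshape((1, nx))
    ramp = np.exp(2j * np.pi * (by * yy / ny + bx * xx / nx))
    return fftn_centered(x * ramp, axes=(-2, -1))


def _rolled_abs_otf(otf_fine: np.ndarray, shift_bins: tuple[float, float]) -> np.ndarray:
    """|OTF| laterally displaced by the nearest integer bins (weight field)."""
    by, bx = int(np.round(shift_bins[0])), int(np.round(shift_bins[1]))
    return np.roll(np.abs(otf_fine), (by, bx), axis=(-2, -1))


def reconstruct_reference(
    stack: RawStack,
    params: IlluminationParams,
    otf: OTFModel,
    wiener_w: float = 0.05,
    include_zero_order: bool = True,
    *,
    combine: str = "wiener",
    apodization_cutoff: float | str | None = "auto",
    upsample: int = 2,
    a_floor: float = A_FLOOR,
) -> SRVolume:
    """Frequency-domain reference reconstruction (stage ``SR_ref``).

    Parameters
    ----------
    combine
        ``"wiener"``: generalized Wiener merge
        ``sum_b H_b * S_b / (sum_b H_b^2 + w)`` with apodization — the
        traditional comparator.  ``"band_sum"``: plain sum of the
        1/a-weighted shifted bands with no transfer weighting and no
        apodization — algebraically identical to the spatial recombination
        (its spectrum is the equivalence target).
    include_zero_order
        Keep the m=0 (widefield) band.  ``False`` reproduces the
        zero-order-removed spatial reconstruction's band content.
    """
    stack.validate()
    if combine not in ("wiener", "band_sum"):
        raise ValueError(f"unknown combine mode {combine!r}")
    nz, ny, nx = stack.data.shape[2:]
    nyf, nxf = upsample * ny, upsample * nx

    big = nz * nyf * nxf > 20_000_000
    cdtype = np.complex64 if big else np.complex128
    use_wiener = combine == "wiener"
    otf_fine = None
    if use_wiener:
        from .simulator import make_otf3d

        otf_fine = np.abs(
            make_otf3d(
                otf.na,
                otf.wavelength_em_nm,
                otf.lateral_pixel_nm / upsample,
                otf.axial_step_nm,
                (nz, nyf, nxf),
            ).otf
        ).astype(np.float32 if big else np.float64)

    num = np.zeros((nz, nyf, nxf), dtype=cdtype)
    den = (
        np.zeros((nz, nyf, nxf), dtype=np.float32 if big else np.float64)
        if use_wiener
        else None
    )

    orders = list(BAND_ORDERS) if include_zero_order else [m for m in BAND_ORDERS if m != 0]
    for j, ang in enumerate(params.angles):
        bands = separate_bands(stack, j, params.phase_steps)
        g = {
            0: 1.0,
            1: 1.0 / max(ang.a1, a_floor),
            -1: 1.0 / max(ang.a1, a_floor),
            2: 1.0 / max(ang.a2, a_floor),
            -2: 1.0 / max(ang.a2, a_floor),
        }
        for m in orders:
            band = bands[BAND_ORDERS.index(m)].astype(cdtype)
            fine = upsample_lateral(band, upsample)
            del band
            if m != 0:
                # move the band to its true frequency position: demodulate by
                # the m-th carrier (includes the starting phase)
                psi = carrier_phase(nyf, nxf, ang.wavevector, ang.phase0, upsample)
                fine *= np.exp(-1j * m * psi)[None, :, :].astype(cdtype)
                del psi
            spec = fftn_centered(fine)
            del fine
            if use_wiener:
                shift = (
                    -m * ang.wavevector[0] * ny,
                    -m * ang.wavevector[1] * nx,
                )
                h = _rolled_abs_otf(otf_fine, shift)
                spec *= h
                spec *= np.asarray(g[m], dtype=spec.real.dtype)
                num += spec
                den += h * h
                del h
            else:
                spec *= np.asarray(g[m], dtype=spec.real.dtype)
                num += spec
            del spec

    if use_wiener:
        den += np.asarray(wiener_w, dtype=den.dtype)
        spec_out = num
        spec_out /= den
        del num, den
        if apodization_cutoff is not None:
            from .freqopt import apodize

            cutoff = apodization_cutoff
            if cutoff == "auto":
                from .freqopt import AUTO_APOD_FACTOR

                cutoff = AUTO_APOD_FACTOR * otf.cutoff_lateral_cpp()
            spec_out = apodize(
                spec_out,
                cutoff,
                upsample=upsample,
                axial_cutoff_cpz=2.0 * otf.cutoff_axial * otf.axial_step_nm
                if nz > 1
                else None,
            )
    else:
        spec_out = num

    out = ifftn_centered(spec_out).real
    if big:
        out = out.astype(np.float32)
    return SRVolume(
        data=out,
        stage="SR_ref",
        lateral_pixel_nm=stack.lateral_pixel_nm / upsample,
        axial_step_nm=stack.axial_step_nm,
    )
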