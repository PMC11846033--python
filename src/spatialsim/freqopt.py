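"""Frequency-domain optimization of the recombined volume (SR0_minus -> SR1).

Three filters act on the DC-centered 3D spectrum of the spatially
recombined volume: a Gaussian notch at the residual illumination peaks
(+-p, +-2p per angle, all axial frequencies), a two-step low-SNR filter
(Wiener-style gain against the coverage-summed effective transfer followed
by out-of-band suppression), and a triangular apodization window.  Every
filter is symmetric about DC, so real input stays real.
"""

from __future__ import annotations

import numpy as np

from ._fft import fftn_centered, freq_axis, ifftn_centered, lateral_freq_grids
from .datamodel import FilterBank, IlluminationParams, OTFModel, SRVolume
from .spatial import A_FLOOR

AXIAL_PAD = 8

#: "auto" apodization cutoff as a multiple of the widefield lateral cutoff
AUTO_APOD_FACTOR = 1.8


def _lateral_radius(shape_yx: tuple[int, int], upsample: int) -> np.ndarray:
    ky, kx = lateral_freq_grids(shape_yx[0], shape_yx[1], upsample)
    return np.sqrt(ky * ky + kx * kx)


def notch_filter(
    spectrum: np.ndarray,
    params: IlluminationParams,
    notch_width: float = 0.01,
    notch_depth: float = 0.95,
    *,
    upsample: int = 2,
) -> np.ndarray:
    """Attenuate residual illumination peaks at +-p and +-2p (all kz).

    Multiplies by ``1 - depth * exp(-d^2 / (2 w^2))`` around each lateral
    peak position, with ``d`` the lateral frequency distance in cycles per
    raw pixel; DC itself is untouched (the zero order was already removed).
    """
    if not 0.0 <= notch_depth <= 1.0:
        raise ValueError(f"notch_depth must be in [0, 1]; got {notch_depth}")
    if notch_depth == 0.0:
        return spectrum
    ny, nx = spectrum.shape[-2], spectrum.shape[-1]
    ky, kx = lateral_freq_grids(ny, nx, upsample)
    filt = np.ones((ny, nx), dtype=np.float64)
    for ang in params.angles:
        py, px = ang.wavevector
        for m in (-2, -1, 1, 2):
            d2 = (ky - m * py) ** 2 + (kx - m * px) ** 2
            filt *= 1.0 - notch_depth * np.exp(-d2 / (2.0 * notch_width**2))
    return spectrum * filt.astype(spectrum.real.dtype)


def apodize(
    spectrum: np.ndarray,
    cutoff_extended: float,
    *,
    upsample: int = 2,
    axial_cutoff_cpz: float | None = None,
) -> np.ndarray:
    """Triangular apodization: 1 at DC, 0 at ``cutoff_extended`` (cycles per
    raw pixel laterally); optionally also a triangular axial window to
    ``axial_cutoff_cpz`` (cycles per z step).  Suppresses hard-edge ringing.
    """
    if cutoff_extended <= 0:
        raise ValueError("cutoff_extended must be positive")
    kr = _lateral_radius(spectrum.shape[-2:], upsample)
    window = np.clip(1.0 - kr / cutoff_extended, 0.0, 1.0)
    out = spectrum * window.astype(spectrum.real.dtype)
    if axial_cutoff_cpz is not None and spectrum.ndim == 3 and spectrum.shape[0] > 1:
        kz = np.abs(freq_axis(spectrum.shape[0]))
        wz = np.clip(1.0 - kz / axial_cutoff_cpz, 0.0, 1.0)
        out *= wz[:, None, None].astype(spectrum.real.dtype)
    return out


def two_step_denoise(
    spectrum: np.ndarray,
    transfer: np.ndarray,
    wiener_w: float,
    *,
    support_mask: np.ndarray | None = None,
    suppression: float = 1.0,
    rolloff_sigma: float | None = None,
    upsample: int = 2,
) -> np.ndarray:
    """Two-step low-SNR filter.

    Step 1 applies the Wiener-style gain ``|H| / (|H|^2 + w)`` against the
    effective (coverage-summed, max-normalized) transfer ``H``.  Step 2
    suppresses out-of-band noise: frequencies outside ``support_mask`` are
    scaled by ``1 - suppression`` (1.0 zeroes them) and an optional mild
    Gaussian high-frequency rolloff ``exp(-kr^2 / (2 sigma^2))`` is applied.
    The output magnitude is non-increasing in ``w`` at every frequency.
    """
    if wiener_w <= 0:
        raise ValueError(f"wiener_w must be positive; got {wiener_w}")
    rdt = spectrum.real.dtype
    h = np.abs(transfer).astype(rdt)
    out = spectrum * (h / (h * h + rdt.type(wiener_w)))
    if support_mask is not None and suppression > 0.0:
        out *= np.where(support_mask, 1.0, 1.0 - suppression).astype(rdt)
    if rolloff_sigma is not None:
        kr = _lateral_radius(spectrum.shape[-2:], upsample)
        out *= np.exp(-(kr * kr) / (2.0 * rolloff_sigma**2)).astype(rdt)
    return out


def effective_transfer(
    params: IlluminationParams,
    otf: OTFModel,
    grid_shape: tuple[int, int, int],
    *,
    upsample: int = 2,
    a_floor: float = A_FLOOR,
) -> np.ndarray:
    """Coverage-summed transfer of the zero-order-removed reconstruction:
    the 1/a-weighted |OTF| footprints displaced to +-p, +-2p for each angle,
    normalized to a maximum of 1.  ``grid_shape`` is the (possibly padded)
    working grid ``(nz, ny_fine, nx_fine)``."""
    from .simulator import make_otf3d

    nz, nyf, nxf = grid_shape
    otf_fine = np.abs(
        make_otf3d(
            otf.na,
            otf.wavelength_em_nm,
            otf.lateral_pixel_nm / upsample,
            otf.axial_step_nm,
            (nz, nyf, nxf),
        ).otf
    )
    ny = nyf // upsample
    nx = nxf // upsample
    acc = np.zeros(grid_shape, dtype=np.float32)
    for ang in params.angles:
        g = {1: 1.0 / max(ang.a1, a_floor), 2: 1.0 / max(ang.a2, a_floor)}
        for m in (-2, -1, 1, 2):
            by = int(np.round(-m * ang.wavevector[0] * ny))
            bx = int(np.round(-m * ang.wavevector[1] * nx))
            acc += np.float32(g[abs(m)]) * np.roll(otf_fine, (by, bx), axis=(-2, -1)).astype(np.float32)
    return acc / acc.max()


def _pad_axial(data: np.ndarray, pad: int, mirror: bool) -> np.ndarray:
    if pad == 0:
        return data
    if mirror:
        return np.pad(data, ((pad, pad), (0, 0), (0, 0)), mode="reflect")
    # stacks too thin to mirror: replicate the edge planes (a zero pad would
    # put a sharp axial edge next to the data and leak along kz)
    return np.pad(data, ((pad, pad), (0, 0), (0, 0)), mode="edge")


def optimize(
    sr0_minus: SRVolume,
    params: IlluminationParams,
    otf: OTFModel,
    filters: FilterBank,
    *,
    upsample: int = 2,
) -> SRVolume:
    """Full frequency-domain optimization: FFT -> notch -> two-step denoise
    -> apodize -> inverse FFT (real part); stage SR0_minus -> SR1.

    Short stacks are padded axially before the 3D FFT (8 mirrored planes
    when z >= 8, edge-replicated planes otherwise) to suppress
    wrap-around, and cropped back afterwards.  With every filter disabled
    (``FilterBank.identity()``) the volume is reproduced to machine
    precision.
    """
    if sr0_minus.stage != "SR0_minus":
        raise ValueError(f"expected stage SR0_minus; got {sr0_minus.stage}")
    big = sr0_minus.data.size > 20_000_000
    cdtype = np.complex64 if big else np.complex128
    data = np.asarray(sr0_minus.data, dtype=np.float32 if big else np.float64)
    nz = data.shape[0]
    pad = min(AXIAL_PAD, max(nz - 1, 1)) if nz > 1 else 0
    mirror = nz >= AXIAL_PAD
    padded = _pad_axial(data, pad, mirror)
    spec = fftn_centered(padded.astype(cdtype))
    del padded

    if filters.notch_depth > 0.0:
        spec = notch_filter(
            spec, params, filters.notch_width, filters.notch_depth, upsample=upsample
        )

    if filters.wiener_w is not None or filters.twostep_suppression > 0.0:
        transfer = effective_transfer(params, otf, spec.shape, upsample=upsample)
        kr = _lateral_radius(spec.shape[-2:], upsample)
        support = kr <= (otf.cutoff_lateral_cpp() + 2.0 * max(a.magnitude for a in params.angles))
        if spec.shape[0] > 1:
            kz = np.abs(freq_axis(spec.shape[0]))
            axial_cut = 2.0 * otf.cutoff_axial * otf.axial_step_nm
            support = support[None, :, :] & (kz[:, None, None] <= axial_cut)
        w = filters.wiener_w if filters.wiener_w is not None else None
        if w is not None:
            spec = two_step_denoise(
                spec,
                transfer,
                w,
                support_mask=support,
                suppression=filters.twostep_suppression,
                rolloff_sigma=filters.twostep_rolloff,
                upsample=upsample,
            )
        elif filters.twostep_suppression > 0.0:
            spec = spec * np.where(support, 1.0, 1.0 - filters.twostep_suppression)

    cutoff = filters.apodization_cutoff
    if cutoff is not None:
        if cutoff == "auto":
            cutoff = AUTO_APOD_FACTOR * otf.cutoff_lateral_cpp()
        axial = 2.0 * otf.cutoff_axial * otf.axial_step_nm if nz > 1 else None
        spec = apodize(spec, float(cutoff), upsample=upsample, axial_cutoff_cpz=axial)

    out = ifftn_centered(spec).real.astype(data.dtype)
    del spec
    if pad:
        out = out[pad : pad + nz]
    return SRVolume(
        data=np.ascontiguousarray(out),
        stage="SR1",
        lateral_pixel_nm=sr0_minus.lateral_pixel_nm,
        axial_step_nm=sr0_minus.axial_step_nm,
    )
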