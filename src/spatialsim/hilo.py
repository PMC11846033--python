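"""HiLo optical sectioning from the raw phase images.

The optical section combines, per angle and per z plane, the low-pass of
the first structured image with the high-pass of the five-phase average
(the widefield image), and averages the three angles to even out
illumination-intensity differences:

    OS(r, z) = (1/3) * sum_theta { Lo[D_theta,1] + Hi[mean_i D_theta,i] }.

Lo and Hi are a complementary Gaussian pair (Lo + Hi = 1 at every
frequency), so an unmodulated acquisition reproduces the widefield image
exactly.  The Lo cutoff defaults to |p|/4 — well below the pattern
frequency, the conventional HiLo crossover; the low-pass acts on the raw
structured image directly (no local-contrast demodulation).
"""

from __future__ import annotations

import numpy as np
import scipy.fft as sfft

from ._fft import lateral_freq_grids
from .datamodel import FilterBank, IlluminationParams, RawStack, SRVolume, N_ANGLES
from .spatial import _upsample_plane  # noqa: F401  (shared upsampling operator)


def make_lohi_pair(
    grid_shape: tuple[int, int], lo_sigma: float
) -> tuple[np.ndarray, np.ndarray]:
    """Complementary Gaussian low/high-pass pair on a raw lateral grid.

    ``Lo(k) = exp(-|k|^2 / (2 sigma^2))`` with ``sigma`` in cycles/pixel,
    DC-centered; ``Hi = 1 - Lo``.
    """
    if lo_sigma <= 0:
        raise ValueError(f"lo_sigma must be positive; got {lo_sigma}")
    ky, kx = lateral_freq_grids(grid_shape[0], grid_shape[1], 1)
    lo = np.exp(-(ky * ky + kx * kx) / (2.0 * lo_sigma**2))
    return lo, 1.0 - lo


def optical_section(
    stack: RawStack,
    filters: FilterBank | None = None,
    params: IlluminationParams | None = None,
    *,
    mode: str | None = None,
    upsample: int = 2,
    a_floor: float = 0.05,
) -> SRVolume:
    """HiLo optical section of a raw stack (stage ``OS``), on the 2x grid.

    Two inputs to the low-pass branch are supported:

    * ``mode="literal"`` — Lo acts on the raw first-phase structured image,
      the combination exactly as written above.  With complementary filters
      an unmodulated acquisition reproduces the widefield image to machine
      precision, but a phase-independent defocused background passes Lo
      unattenuated, so this variant does not section smooth backgrounds.
    * ``mode="amplitude"`` — Lo acts on the per-pixel first-harmonic
      amplitude ``|(2/5) sum_i D_i exp(-i phi_i)| / a1`` (the classic
      OS-SIM section): only in-focus content is pattern-modulated, so the
      low-frequency part of the section is genuinely background-free.

    ``mode=None`` resolves to ``filters.hilo_mode`` when a filter bank is
    given (the reconstruction pipeline defaults to ``"amplitude"``), else
    ``"literal"`` (the printed combination).  The Lo sigma comes from
    ``filters.lo_sigma`` if set, otherwise from the |p|/4 rule.  Filtering
    is per-z-plane 2D; the result is Fourier-upsampled laterally to match
    the SR grids.
    """
    stack.validate()
    if mode is None:
        mode = filters.hilo_mode if filters is not None else "literal"
    if mode not in ("literal", "amplitude"):
        raise ValueError(f"unknown optical-section mode {mode!r}")
    lo_sigma = filters.lo_sigma if filters is not None else None
    if lo_sigma is None:
        if params is None:
            raise ValueError("need filters.lo_sigma or params for the |p|/4 rule")
        lo_sigma = np.mean([a.magnitude for a in params.angles]) / 4.0
    if mode == "amplitude" and params is None:
        raise ValueError("mode='amplitude' needs params (phase steps and a1)")
    nz, ny, nx = stack.data.shape[2:]
    lo, hi = make_lohi_pair((ny, nx), float(lo_sigma))
    lo_n = np.fft.ifftshift(lo)
    hi_n = np.fft.ifftshift(hi)

    data = stack.data
    big = nz * ny * nx * upsample * upsample > 20_000_000
    out = np.empty((nz, upsample * ny, upsample * nx),
                   dtype=np.float32 if big else np.float64)
    if params is not None:
        steps = np.asarray(params.phase_steps)
    # in amplitude mode the section is band-limited to the detection
    # support: the magnitude operation rectifies noise across the whole
    # sampling band, and content beyond the widefield cutoff is pure noise
    band_n = None
    if mode == "amplitude":
        cutoff_cpp = 2.0 * stack.na / stack.wavelength_em_nm * stack.lateral_pixel_nm
        ky, kx = lateral_freq_grids(ny, nx, 1)
        kr = np.sqrt(ky * ky + kx * kx)
        edge0 = 0.85 * cutoff_cpp
        band = np.clip((cutoff_cpp - kr) / (cutoff_cpp - edge0), 0.0, 1.0)
        band = 0.5 - 0.5 * np.cos(np.pi * band)
        band_n = np.fft.ifftshift(band)
    for z in range(nz):
        acc = np.zeros((ny, nx), dtype=np.float64)
        for j in range(N_ANGLES):
            widefield = data[j, :, z].mean(axis=0, dtype=np.float64)
            if mode == "literal":
                structured = data[j, 0, z].astype(np.float64)
            else:
                phasor = np.tensordot(
                    np.exp(-1j * steps), data[j, :, z].astype(np.float64), axes=(0, 0)
                )
                structured = (2.0 / 5.0) * np.abs(phasor)
                structured /= max(params.angles[j].a1, a_floor)
            acc += sfft.ifft2(lo_n * sfft.fft2(structured)).real
            acc += sfft.ifft2(hi_n * sfft.fft2(widefield)).real
        acc /= N_ANGLES
        if band_n is not None:
            acc = sfft.ifft2(band_n * sfft.fft2(acc)).real
        out[z] = _upsample_plane(acc, upsample)
    return SRVolume(
        data=out,
        stage="OS",
        lateral_pixel_nm=stack.lateral_pixel_nm / upsample,
        axial_step_nm=stack.axial_step_nm,
    )
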