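"""Centered-FFT helpers shared by the simulator, both reconstructors and filters.

All public helpers work on DC-centered spectra (``fftshift`` layout).  The
lateral Fourier upsampler is a single linear operator used by *both* the
spatial recombination path and the frequency-domain oracle, so that their
outputs are comparable to machine precision.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as sfft


def fftn_centered(x: np.ndarray, axes=None) -> np.ndarray:
    """FFT with DC-centered output (input in natural layout)."""
    return np.fft.fftshift(sfft.fftn(x, axes=axes), axes=axes)


def ifftn_centered(X: np.ndarray, axes=None) -> np.ndarray:
    """Inverse FFT of a DC-centered spectrum, natural-layout output."""
    return sfft.ifftn(np.fft.ifftshift(X, axes=axes), axes=axes)


def freq_axis(n: int, d: float = 1.0) -> np.ndarray:
    """DC-centered frequency axis in cycles per unit ``d``."""
    return np.fft.fftshift(np.fft.fftfreq(n, d=d))


def _pad_centered_axis(spec: np.ndarray, axis: int, n_out: int) -> np.ndarray:
    """Zero-pad a DC-centered spectrum along ``axis`` from n to ``n_out``.

    For even input length the (unpaired) Nyquist bin at index 0 of the
    centered layout is split half-and-half between +n/2 and -n/2 of the
    output, which keeps real signals exactly real after upsampling.
    """
    n = spec.shape[axis]
    if n_out < n:
        raise ValueError("padding target smaller than input")
    if n_out == n:
        return spec
    shape = list(spec.shape)
    shape[axis] = n_out
    out = np.zeros(shape, dtype=np.promote_types(spec.dtype, np.complex64))
    lo = (n_out - n) // 2
    src = [slice(None)] * spec.ndim
    dst = [slice(None)] * spec.ndim
    src[axis] = slice(0, n)
    dst[axis] = slice(lo, lo + n)
    out[tuple(dst)] = spec[tuple(src)]
    if n % 2 == 0:
        # centered index 0 holds the -n/2 == +n/2 Nyquist bin: split it
        nyq = [slice(None)] * spec.ndim
        nyq[axis] = slice(0, 1)
        half = 0.5 * spec[tuple(nyq)]
        at_lo = [slice(None)] * spec.ndim
        at_lo[axis] = slice(lo, lo + 1)
        out[tuple(at_lo)] = half
        at_hi = [slice(None)] * spec.ndim
        at_hi[axis] = slice(lo + n, lo + n + 1)
        out[tuple(at_hi)] = half
    return out


def pad_centered_lateral(spec: np.ndarray, factor: int = 2) -> np.ndarray:
    """Zero-pad the last two axes of a DC-centered spectrum by ``factor``."""
    out = spec
    for axis in (-2, -1):
        out = _pad_centered_axis(out, axis % spec.ndim, spec.shape[axis] * factor)
    return out


def crop_centered_lateral(spec: np.ndarray, n_out: int) -> np.ndarray:
    """Crop the last two axes of a DC-centered spectrum to ``n_out`` each."""
    ny, nx = spec.shape[-2], spec.shape[-1]
    y0 = (ny - n_out) // 2
    x0 = (nx - n_out) // 2
    return spec[..., y0 : y0 + n_out, x0 : x0 + n_out]


def upsample_lateral(vol: np.ndarray, factor: int = 2) -> np.ndarray:
    """Band-limited lateral upsampling of (..., y, x) by Fourier zero-padding.

    Mean-preserving (the interpolant passes through the original samples up
    to the usual Nyquist-bin symmetrization).  Real input -> real output;
    complex input stays complex.  The z axis (if any) is untouched.
    """
    was_real = np.isrealobj(vol)
    spec = np.fft.fftshift(sfft.fftn(vol, axes=(-2, -1)), axes=(-2, -1))
    spec = pad_centered_lateral(spec, factor)
    out = sfft.ifftn(np.fft.ifftshift(spec, axes=(-2, -1)), axes=(-2, -1))
    out *= factor * factor  # keep sample amplitudes (mean preserved)
    if was_real:
        return np.ascontiguousarray(out.real)
    return np.ascontiguousarray(out)


def lateral_coords(n_fine: int, upsample: int = 1) -> np.ndarray:
    """Pixel coordinates of a (possibly upsampled) lateral axis, in *raw*
    pixel units: ``0, 1/u, 2/u, ...`` for upsample factor ``u``."""
    return np.arange(n_fine, dtype=np.float64) / float(upsample)


def carrier_phase(
    ny: int, nx: int, wavevector: tuple[float, float], phase0: float, upsample: int = 1
) -> np.ndarray:
    """2D total pattern phase psi(r) = 2*pi*(ky*y + kx*x) + phase0.

    ``wavevector`` in cycles per raw pixel; the grid may be ``upsample``-times
    finer than the raw grid (coordinates stay in raw-pixel units).
    """
    ky, kx = wavevector
    y = lateral_coords(ny, upsample)[:, None]
    x = lateral_coords(nx, upsample)[None, :]
    return 2.0 * np.pi * (ky * y + kx * x) + phase0


def lateral_freq_grids(ny: int, nx: int, upsample: int = 1):
    """DC-centered (ky, kx) grids in cycles per *raw* pixel for a grid that is
    ``upsample``-times finer laterally than the raw grid."""
    ky = freq_axis(ny, d=1.0 / upsample)[:, None]
    kx = freq_axis(nx, d=1.0 / upsample)[None, :]
    return ky, kx
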