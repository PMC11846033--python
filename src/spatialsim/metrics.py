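"""Quantitative evaluation: SBR, SNR and image-decorrelation resolution.

SBR and SNR follow the usual region-of-interest definitions in dB; the
resolution estimate implements image decorrelation analysis: the highest
frequency at which the image spectrum remains correlated with its
phase-only (unit-magnitude) version across a sweep of low-pass radii and
Gaussian high-pass pre-filters.  The method is parameter-free but requires
noise in the image — on a noise-free image the decorrelation curves have
no interior peak and the resolution is reported as undefined.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as sfft


class UndefinedMetricError(ValueError):
    """The requested metric is undefined for this input (e.g. no noise)."""


def _normalize_minmax(image: np.ndarray) -> np.ndarray:
    lo, hi = float(image.min()), float(image.max())
    if hi <= lo:
        raise ValueError("image is constant; metrics undefined")
    return (image - lo) / (hi - lo)


def _check_masks(image: np.ndarray, *masks: np.ndarray) -> list[np.ndarray]:
    out = []
    for m in masks:
        m = np.asarray(m).astype(bool)
        if m.shape != image.shape:
            raise ValueError(f"mask shape {m.shape} != image shape {image.shape}")
        if not m.any():
            raise ValueError("mask is empty")
        out.append(m)
    if len(out) == 2 and (out[0] & out[1]).any():
        raise ValueError("masks overlap; regions must be disjoint")
    return out


def sbr_db(image: np.ndarray, signal_mask: np.ndarray, background_mask: np.ndarray) -> float:
    """Signal-to-background ratio in dB on the min-max normalized image:
    ``10*log10(mean(signal region) / mean(background region))``."""
    image = np.asarray(image, dtype=np.float64)
    sig, bg = _check_masks(image, signal_mask, background_mask)
    norm = _normalize_minmax(image)
    mb = norm[bg].mean()
    if mb <= 0:
        raise ValueError("background mean is zero; SBR undefined")
    return float(10.0 * np.log10(norm[sig].mean() / mb))


def snr_db(image: np.ndarray, signal_mask: np.ndarray, noise_mask: np.ndarray) -> float:
    """Signal-to-noise ratio in dB:
    ``10*log10((mean(signal) - mean(noise)) / std(noise))``.

    Raises
    ------
    UndefinedMetricError
        if the signal mean does not exceed the noise mean (the log argument
        would be non-positive) or the noise region has zero spread.
    """
    image = np.asarray(image, dtype=np.float64)
    sig, noi = _check_masks(image, signal_mask, noise_mask)
    ms, mn = image[sig].mean(), image[noi].mean()
    sn = image[noi].std()
    if sn <= 0:
        raise UndefinedMetricError("noise region has zero standard deviation")
    if ms <= mn:
        raise UndefinedMetricError(
            f"signal mean ({ms:.4g}) does not exceed noise mean ({mn:.4g}); SNR undefined"
        )
    return float(10.0 * np.log10((ms - mn) / sn))


def _edge_window(shape: tuple[int, int], border: int) -> np.ndarray:
    """Cosine taper to zero over ``border`` pixels at each image edge."""
    wins = []
    for n in shape:
        w = np.ones(n)
        if border > 0:
            ramp = 0.5 - 0.5 * np.cos(np.pi * np.arange(border) / border)
            w[:border] = ramp
            w[-border:] = ramp[::-1]
        wins.append(w)
    return wins[0][:, None] * wins[1][None, :]


def _curve_peak(d: np.ndarray) -> tuple[int, float] | None:
    """Global maximum of a decorrelation curve, ignoring a maximum sitting
    on the trailing edge (no interior peak -> None)."""
    dd = d
    while dd.size > 2:
        i = int(np.argmax(dd))
        if i < dd.size - 1:
            return i, float(dd[i])
        dd = dd[:-1]
    return None


def decorrelation_resolution(
    image: np.ndarray,
    lateral_pixel_nm: float,
    *,
    n_radii: int = 100,
    n_highpass: int = 10,
    edge_border: int | None = None,
    amplitude_threshold: float = 1e-3,
) -> float:
    """Image-decorrelation resolution estimate of a single 2D plane, in nm.

    The decorrelation function ``d(r)`` correlates the image spectrum with
    its phase-only version restricted to frequencies below radius ``r``
    (normalized to Nyquist).  The cutoff ``kc`` is the largest peak
    frequency across the unfiltered curve and ``n_highpass`` Gaussian
    high-pass pre-filtered variants; resolution = ``2 * pixel / kc``.

    Raises
    ------
    UndefinedMetricError
        if no decorrelation peak exists (typically a noise-free image).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D plane; got {image.ndim}D")
    ny, nx = image.shape
    if edge_border is None:
        edge_border = max(8, min(ny, nx) // 16)
    img = (image - image.mean()) * _edge_window(image.shape, edge_border)

    spec = np.fft.fftshift(sfft.fft2(img))
    ky = np.fft.fftshift(np.fft.fftfreq(ny))[:, None] / 0.5
    kx = np.fft.fftshift(np.fft.fftfreq(nx))[None, :] / 0.5
    kn = np.sqrt(ky * ky + kx * kx)  # normalized: 1.0 == Nyquist

    flat_k = kn.ravel()
    order = np.argsort(flat_k)
    k_sorted = flat_k[order]
    mag = np.abs(spec).ravel()[order]
    mag[0] = 0.0  # exclude DC
    in_disk = k_sorted <= 1.0
    counts_all = np.cumsum(in_disk.astype(np.float64))

    radii = np.linspace(1.0 / n_radii, 1.0, n_radii)
    idx = np.searchsorted(k_sorted, radii, side="right")

    # high-pass strengths: 1 - exp(-kn^2 / (2 s^2)) in normalized frequency
    sigmas = np.geomspace(0.08, 1.0, n_highpass)
    weights = [np.ones_like(k_sorted)] + [
        1.0 - np.exp(-(k_sorted * k_sorted) / (2.0 * s * s)) for s in sigmas
    ]

    best_kc = 0.0
    best_amp = 0.0
    found = False
    for w in weights:
        m = mag * w
        cum_num = np.cumsum(m)
        total = np.sqrt(np.sum((m * in_disk) ** 2))
        if total <= 0:
            continue
        num = cum_num[idx - 1]
        cnt = counts_all[idx - 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            d = num / (total * np.sqrt(cnt))
        d = np.nan_to_num(d)
        peak = _curve_peak(d)
        if peak is None:
            continue
        i, amp = peak
        if amp >= amplitude_threshold and radii[i] > best_kc:
            best_kc = float(radii[i])
            best_amp = amp
            found = True
    if not found or best_kc <= 0:
        raise UndefinedMetricError(
            "no decorrelation peak found; resolution undefined "
            "(the method requires noise in the image)"
        )
    del best_amp
    return float(2.0 * lateral_pixel_nm / best_kc)
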