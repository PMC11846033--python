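"""Final fusion: SR2 = SR1 + w * OS, clamped at zero.

The optimized high-resolution volume carries no unmodulated (zero-order)
content; the optical section restores in-focus low-frequency structure.
Because the two volumes come from differently normalized pipelines, the
optical section is scaled by an explicit weight before the sum.  The
pipeline default matches the two spectra over a mid-frequency crossover
annulus where both carry content, so the section blends in at the
resolution-neutral level; a DC-matching weight (section sum equals the
removed zero-order sum) is also provided but can swamp the
high-resolution band when the section is widefield-bright.  The clamp is
applied after the sum, never before.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as sfft

from .datamodel import SRVolume


def dc_matching_weight(os_volume: SRVolume, wf_dc: float) -> float:
    """Weight that matches the optical section's DC (sum) to the removed
    zero-order DC ``wf_dc`` (the widefield volume sum on the same grid)."""
    os_dc = float(np.sum(os_volume.data))
    if os_dc <= 0:
        raise ValueError(f"optical-section DC must be positive; got {os_dc}")
    return wf_dc / os_dc


def spectral_matching_weight(
    sr1: SRVolume, os: SRVolume, *, annulus: tuple[float, float] = (0.15, 0.25)
) -> float:
    """Weight that equalizes the two volumes' spectral magnitude over a
    mid-frequency annulus (bounds in Nyquist units of the shared grid),
    evaluated on the central z plane.  Inside both bands and above the
    DC/background region, this is the crossover level at which the
    section's low frequencies hand over to the reconstruction's high
    frequencies without rescaling either band.
    """
    sr1.require_same_grid(os)
    z = sr1.data.shape[0] // 2
    f1 = np.abs(np.fft.fftshift(sfft.fft2(np.asarray(sr1.data[z], dtype=np.float64))))
    f2 = np.abs(np.fft.fftshift(sfft.fft2(np.asarray(os.data[z], dtype=np.float64))))
    ny, nx = f1.shape
    ky = np.fft.fftshift(np.fft.fftfreq(ny))[:, None] / 0.5
    kx = np.fft.fftshift(np.fft.fftfreq(nx))[None, :] / 0.5
    kn = np.hypot(ky, kx)
    lo, hi = annulus
    mask = (kn >= lo) & (kn <= hi)
    e1 = float(np.linalg.norm(f1[mask]))
    e2 = float(np.linalg.norm(f2[mask]))
    if e2 <= 0:
        raise ValueError("optical section has no energy in the crossover annulus")
    return e1 / e2


def fuse(
    sr1: SRVolume,
    os: SRVolume,
    os_weight: float | None = None,
    *,
    wf_dc: float | None = None,
) -> SRVolume:
    """Fuse the optimized SR volume with the optical section (stage SR2).

    ``os_weight=None`` uses DC matching via ``wf_dc`` when provided, else
    1.0 (the plain unweighted sum).  Grids must match exactly.
    """
    if sr1.stage not in ("SR1", "SR0_minus"):
        raise ValueError(f"first argument must be stage SR1; got {sr1.stage}")
    if os.stage != "OS":
        raise ValueError(f"second argument must be stage OS; got {os.stage}")
    sr1.require_same_grid(os)
    if os_weight is None:
        os_weight = dc_matching_weight(os, wf_dc) if wf_dc is not None else 1.0
    fused = sr1.data + os_weight * os.data
    return SRVolume(
        data=np.maximum(fused, 0.0),
        stage="SR2",
        lateral_pixel_nm=sr1.lateral_pixel_nm,
        axial_step_nm=sr1.axial_step_nm,
    )
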