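"""Synthetic 3D-SIM acquisition generator with ground truth.

The forward model is three-beam-style laterally sinusoidal excitation with
first and second harmonics,

    E_i(r) = I0 * [1 + a1*cos(psi(r) + phi_i) + a2*cos(2*psi(r) + 2*phi_i)],

``psi(r) = 2*pi*p.r + phase0``, applied to a fluorophore density, blurred by
a scalar-diffraction 3D PSF, plus an optional smooth defocused-background
term and Poisson + Gaussian read noise.  No explicit axial pattern
modulation is simulated (the harmonics are purely lateral).

Modulation and blurring are carried out on a 2x-lateral fine grid and
Fourier-cropped back to the camera grid: the second-harmonic carrier can
exceed the raw Nyquist frequency, so raw-grid generation would alias the
+-2 bands, while the detected image itself is OTF-bandlimited and survives
the crop exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft as sfft
from scipy.ndimage import gaussian_filter

from ._fft import (
    carrier_phase,
    crop_centered_lateral,
    fftn_centered,
    ifftn_centered,
    upsample_lateral,
)
from .datamodel import (
    AngleParams,
    IlluminationParams,
    OTFModel,
    RawStack,
    N_ANGLES,
    N_PHASES,
)

# Default optics of the simulator, calibrated once so that the *widefield*
# image-decorrelation resolution of the default point phantom lands near
# 237 nm, then frozen (see docs/methods.md).
DEFAULT_NA = 1.25
DEFAULT_WAVELENGTH_NM = 525.0
DEFAULT_LATERAL_PIXEL_NM = 62.5
DEFAULT_AXIAL_STEP_NM = 125.0
DEFAULT_PATTERN_FRACTION = 0.8  # |p| as a fraction of the lateral cutoff
DEFAULT_ANGLES_DEG = (5.0, 65.0, 125.0)
DEFAULT_PHASE0 = (0.0, 1.0, 2.0)
DEFAULT_A1 = 0.9
DEFAULT_A2 = 0.45
IMMERSION_INDEX = 1.518


@dataclass
class NoiseModel:
    """Shot + read noise: Poisson at ``photon_budget`` peak photons followed
    by additive Gaussian read noise of ``read_sigma`` electrons."""

    photon_budget: float = 500.0
    read_sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.photon_budget <= 0:
            raise ValueError(f"photon_budget must be positive; got {self.photon_budget}")
        if self.read_sigma < 0:
            raise ValueError(f"read_sigma must be >= 0; got {self.read_sigma}")


@dataclass
class Phantom:
    """A ground-truth fluorophore density with generation metadata."""

    volume: np.ndarray  # (z, y, x), density >= 0
    kind: str
    lateral_pixel_nm: float
    axial_step_nm: float
    truth: dict = field(default_factory=dict)


def _splat(volume: np.ndarray, z: float, y: float, x: float, amp: float) -> None:
    """Deposit ``amp`` at a fractional voxel position by trilinear splatting."""
    nz, ny, nx = volume.shape
    z0, y0, x0 = int(np.floor(z)), int(np.floor(y)), int(np.floor(x))
    fz, fy, fx = z - z0, y - y0, x - x0
    for dz, wz in ((0, 1 - fz), (1, fz)):
        for dy, wy in ((0, 1 - fy), (1, fy)):
            for dx, wx in ((0, 1 - fx), (1, fx)):
                w = wz * wy * wx
                if w == 0.0:
                    continue
                zi, yi, xi = z0 + dz, y0 + dy, x0 + dx
                if 0 <= zi < nz and 0 <= yi < ny and 0 <= xi < nx:
                    volume[zi, yi, xi] += amp * w


def make_phantom(
    kind: str,
    grid_shape: tuple[int, int, int],
    spacing_nm: float,
    rng_seed: int | None = None,
    *,
    lateral_pixel_nm: float = DEFAULT_LATERAL_PIXEL_NM,
    axial_step_nm: float = DEFAULT_AXIAL_STEP_NM,
    amplitude: float = 1.0,
    site_pitch_px: int = 32,
    volume: np.ndarray | None = None,
) -> Phantom:
    """Build a test phantom of paired sub-diffraction structures.

    Parameters
    ----------
    kind
        ``point``: randomly placed point pairs whose pair axis cycles
        through x, y and z; ``line``: pairs of parallel lines along x;
        ``circle``: a thin ring of diameter ``spacing_nm`` at the focal
        plane; ``custom``: use ``volume`` as given.
    grid_shape
        ``(nz, ny, nx)`` voxels, matching the target acquisition geometry.
    spacing_nm
        Pair separation (point/line) or ring diameter (circle) in nm.
        Zero collapses a pair into a single (merged) structure.
    rng_seed
        Seeds the random placement of point-pair sites (``None`` uses a
        fixed default seed; generation is always deterministic).

    Raises
    ------
    ValueError
        if ``0 < spacing_nm`` is smaller than one voxel, so the requested
        separation cannot be represented on the grid.
    """
    nz, ny, nx = grid_shape
    if kind == "custom":
        if volume is None:
            raise ValueError("kind='custom' requires a volume")
        v = np.asarray(volume, dtype=np.float64)
        if v.shape != tuple(grid_shape):
            raise ValueError(f"volume shape {v.shape} != grid_shape {grid_shape}")
        if (v < 0).any():
            raise ValueError("phantom density must be non-negative")
        return Phantom(v, "custom", lateral_pixel_nm, axial_step_nm, {})

    if spacing_nm < 0:
        raise ValueError("spacing_nm must be >= 0")
    sep_px = spacing_nm / lateral_pixel_nm
    sep_pz = spacing_nm / axial_step_nm
    if 0 < spacing_nm < min(lateral_pixel_nm, axial_step_nm):
        raise ValueError(
            f"spacing {spacing_nm} nm is below one voxel "
            f"({lateral_pixel_nm} x {axial_step_nm} nm)"
        )

    v = np.zeros((nz, ny, nx), dtype=np.float64)
    truth: dict = {"spacing_nm": spacing_nm, "merged": spacing_nm == 0.0}
    rng = np.random.default_rng(rng_seed) if rng_seed is not None else None

    if kind == "point":
        # pair sites at random positions: a regular lattice would put Bragg
        # harmonics into the spectrum that alias pattern-frequency searches
        if rng is None:
            rng = np.random.default_rng(0)
        margin = site_pitch_px // 2
        n_sites = max(1, ((ny - 2 * margin) // site_pitch_px)
                      * ((nx - 2 * margin) // site_pitch_px))
        centers = []
        axis_cycle = ("x", "y", "z") if nz >= 3 else ("x", "y")
        zc = nz // 2
        for i_site in range(n_sites):
            ax = axis_cycle[i_site % len(axis_cycle)]
            cy = rng.uniform(margin, ny - margin)
            cx = rng.uniform(margin, nx - margin)
            cz = float(zc)
            if ax == "x":
                pts = [(cz, cy, cx - sep_px / 2), (cz, cy, cx + sep_px / 2)]
            elif ax == "y":
                pts = [(cz, cy - sep_px / 2, cx), (cz, cy + sep_px / 2, cx)]
            else:
                pts = [(cz - sep_pz / 2, cy, cx), (cz + sep_pz / 2, cy, cx)]
            if spacing_nm == 0.0:
                pts = [pts[0]]
            for (pz, py, px) in pts:
                _splat(v, pz, py, px, amplitude)
                centers.append(
                    (pz * axial_step_nm, py * lateral_pixel_nm, px * lateral_pixel_nm)
                )
        truth["centers_nm"] = centers
    elif kind == "line":
        zc = nz // 2
        n_groups = max(1, nx // (4 * site_pitch_px))
        positions = []
        for g in range(n_groups):
            xc = (g + 0.5) * nx / n_groups
            xs = [xc] if spacing_nm == 0.0 else [xc - sep_px / 2, xc + sep_px / 2]
            for x in xs:
                for y in range(ny // 8, 7 * ny // 8):
                    _splat(v, float(zc), float(y), x, amplitude)
                positions.append(x * lateral_pixel_nm)
        truth["line_x_nm"] = positions
    elif kind == "circle":
        zc = nz // 2
        r_px = (spacing_nm / 2.0) / lateral_pixel_nm
        cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
        if r_px <= 0:
            _splat(v, float(zc), cy, cx, amplitude)
            truth["radius_nm"] = 0.0
        else:
            # arc-length deposition: total integrated density = amp * 2*pi*r
            n_steps = max(16, int(np.ceil(2 * np.pi * r_px / 0.1)))
            dtheta = 2 * np.pi / n_steps
            arc = r_px * dtheta
            for t in np.arange(n_steps) * dtheta:
                _splat(v, float(zc), cy + r_px * np.sin(t), cx + r_px * np.cos(t),
                       amplitude * arc)
            truth["radius_nm"] = r_px * lateral_pixel_nm
            truth["center_yx_nm"] = (cy * lateral_pixel_nm, cx * lateral_pixel_nm)
            truth["integrated_density"] = amplitude * 2 * np.pi * r_px
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")

    return Phantom(v, kind, lateral_pixel_nm, axial_step_nm, truth)


def make_otf3d(
    na: float,
    wavelength_em_nm: float,
    lateral_pixel_nm: float,
    axial_step_nm: float,
    grid_shape: tuple[int, int, int],
    *,
    immersion_index: float = IMMERSION_INDEX,
) -> OTFModel:
    """Scalar-diffraction 3D OTF/PSF pair on the given (z, y, x) grid.

    The amplitude PSF is propagated plane-by-plane from a hard circular
    pupil (angular-spectrum method with spherical defocus phase); the
    intensity PSF is its squared modulus, so the OTF carries the classic
    missing-cone structure.  The PSF is sum-normalized, hence OTF(DC) = 1.
    """
    if not 0 < na <= 1.52:
        raise ValueError(f"na must be in (0, 1.52]; got {na}")
    if na > immersion_index:
        raise ValueError(f"na ({na}) exceeds immersion index ({immersion_index})")
    if wavelength_em_nm <= 0:
        raise ValueError("wavelength must be positive")
    nz, ny, nx = grid_shape
    if min(ny, nx) < 16:
        raise ValueError(f"lateral grid {ny}x{nx} too small to contain the PSF")

    ky = np.fft.fftfreq(ny, d=lateral_pixel_nm)[:, None]
    kx = np.fft.fftfreq(nx, d=lateral_pixel_nm)[None, :]
    kr2 = ky * ky + kx * kx
    k_na = na / wavelength_em_nm
    k0 = immersion_index / wavelength_em_nm
    pupil = (kr2 <= k_na * k_na).astype(np.float64)
    kz = np.sqrt(np.maximum(k0 * k0 - kr2, 0.0))

    # single precision for the stored pair: the PSF/OTF are smooth, and the
    # large (fine/padded) grids the filters request would otherwise dominate
    # the memory budget
    z = (np.arange(nz) - nz // 2) * axial_step_nm
    psf = np.empty((nz, ny, nx), dtype=np.float32)
    for iz, zval in enumerate(z):
        field = sfft.ifft2(pupil * np.exp(2j * np.pi * kz * zval))
        plane = np.abs(field) ** 2
        psf[iz] = np.fft.fftshift(plane)
    psf /= psf.sum(dtype=np.float64)

    otf = fftn_centered(np.fft.ifftshift(psf).astype(np.complex64))
    cutoff_lateral = 2.0 * na / wavelength_em_nm
    cutoff_axial = (immersion_index - np.sqrt(immersion_index**2 - na**2)) / wavelength_em_nm
    return OTFModel(
        otf=otf,
        psf=psf,
        cutoff_lateral=cutoff_lateral,
        cutoff_axial=cutoff_axial,
        na=na,
        wavelength_em_nm=wavelength_em_nm,
        lateral_pixel_nm=lateral_pixel_nm,
        axial_step_nm=axial_step_nm,
    )


def default_illumination(
    otf: OTFModel,
    *,
    pattern_fraction: float = DEFAULT_PATTERN_FRACTION,
    angles_deg: tuple[float, float, float] = DEFAULT_ANGLES_DEG,
    phase0: tuple[float, float, float] = DEFAULT_PHASE0,
    a1: float = DEFAULT_A1,
    a2: float = DEFAULT_A2,
    snap_to_grid: bool = True,
) -> IlluminationParams:
    """Illumination defaults: |p| at ``pattern_fraction`` of the lateral
    cutoff, three orientations 60 degrees apart.

    With ``snap_to_grid`` the wavevectors are rounded to integer cycles per
    field of view (the OTF's lateral grid), so the simulated patterns are
    continuous across the periodic boundary — without this, the boundary
    phase jump leaks into every frequency bin of the simulated data.
    """
    p_mag = pattern_fraction * otf.cutoff_lateral_cpp()
    n_lat = otf.psf.shape[-1]
    angles = []
    for j in range(N_ANGLES):
        th = np.deg2rad(angles_deg[j])
        p = np.array([p_mag * np.sin(th), p_mag * np.cos(th)])
        if snap_to_grid:
            p = np.round(p * n_lat) / n_lat
        angles.append(
            AngleParams(
                wavevector=(float(p[0]), float(p[1])),
                phase0=phase0[j],
                a1=a1,
                a2=a2,
            )
        )
    return IlluminationParams(angles=tuple(angles))


def _hermitian_flip(spec: np.ndarray) -> np.ndarray:
    """conj(S(-k)) for a DC-centered spectrum (real-space conjugation)."""
    out = spec[::-1, ::-1, ::-1].conj()
    shifts = [1 if n % 2 == 0 else 0 for n in spec.shape]
    if any(shifts):
        out = np.roll(out, shifts, axis=(0, 1, 2))
    return out


def simulate_acquisition(
    phantom: Phantom,
    params: IlluminationParams,
    otf: OTFModel,
    background_strength: float = 0.0,
    noise: NoiseModel | None = None,
    rng_seed: int = 0,
    *,
    background_sigma_px: float = 16.0,
    background_sigma_z: float = 4.0,
) -> RawStack:
    """Simulate a 3 angle x 5 phase 3D-SIM acquisition of ``phantom``.

    ``otf`` must live on the phantom's (z, y, x) grid; it defines the optics
    (a matching fine-grid OTF is generated internally for anti-aliased
    modulation).  The defocused background is the widefield image smoothed
    by a wide Gaussian (an effective heavily-widened PSF), scaled by
    ``background_strength`` and added identically to every phase, so it is
    phase-independent by construction.  Deterministic for a fixed
    ``rng_seed``.
    """
    v = np.asarray(phantom.volume, dtype=np.float64)
    if v.shape != otf.psf.shape:
        raise ValueError(f"phantom grid {v.shape} != OTF grid {otf.psf.shape}")
    nz, ny, nx = v.shape
    if params.phase_steps is None or len(params.phase_steps) != N_PHASES:
        raise ValueError("params must carry 5 phase steps")

    # fine-grid forward model; single precision on the large arrays
    big = nz * ny * nx > 2_000_000
    cdtype = np.complex64 if big else np.complex128
    fdtype = np.float32 if big else np.float64
    v_fine = upsample_lateral(v, 2).astype(fdtype)
    otf_fine = np.ascontiguousarray(
        make_otf3d(
            otf.na,
            otf.wavelength_em_nm,
            otf.lateral_pixel_nm / 2.0,
            otf.axial_step_nm,
            (nz, 2 * ny, 2 * nx),
        ).otf.real.astype(fdtype)
    )  # aberration-free symmetric PSF -> real OTF

    spec_v = fftn_centered(v_fine.astype(cdtype))
    m0 = np.ascontiguousarray(crop_centered_lateral(spec_v * otf_fine, ny))
    wf = ifftn_centered(m0).real  # widefield volume, shared across angles

    stack = np.empty((N_ANGLES, N_PHASES, nz, ny, nx), dtype=np.float32)
    steps = np.asarray(params.phase_steps)
    for j, ang in enumerate(params.angles):
        psi = carrier_phase(2 * ny, 2 * nx, ang.wavevector, ang.phase0, upsample=2)
        bands = {0: m0}
        for m in (1, 2):
            mod = v_fine * np.exp(1j * m * psi)[None, :, :].astype(cdtype)
            bands[m] = np.ascontiguousarray(
                crop_centered_lateral(fftn_centered(mod) * otf_fine, ny)
            )
            del mod
        del psi
        bands[-1] = _hermitian_flip(bands[1])
        bands[-2] = _hermitian_flip(bands[2])
        for i in range(N_PHASES):
            phi = steps[i]
            spec = ang.i0 * (
                bands[0]
                + 0.5 * ang.a1 * (np.exp(1j * phi) * bands[1] + np.exp(-1j * phi) * bands[-1])
                + 0.5 * ang.a2 * (np.exp(2j * phi) * bands[2] + np.exp(-2j * phi) * bands[-2])
            )
            stack[j, i] = ifftn_centered(spec.astype(cdtype)).real
            del spec
        del bands
    del spec_v, v_fine, otf_fine

    if background_strength != 0.0:
        bg = background_strength * gaussian_filter(
            np.asarray(wf, dtype=np.float32),
            sigma=(background_sigma_z, background_sigma_px, background_sigma_px),
            mode="nearest",
        )
        stack += bg[None, None]

    # detected intensities are photon-count-like: clamp band-limited
    # interpolation ringing at zero before drawing shot noise
    np.maximum(stack, 0.0, out=stack)

    if noise is not None:
        rng = np.random.default_rng(rng_seed)
        peak = float(stack.max())
        if peak <= 0:
            raise ValueError("cannot apply shot noise to an all-zero acquisition")
        scale = noise.photon_budget / peak
        # chunk per (angle, phase) image to bound the temporary arrays
        for j in range(N_ANGLES):
            for i in range(N_PHASES):
                img = rng.poisson(stack[j, i].astype(np.float64) * scale).astype(
                    np.float32
                )
                if noise.read_sigma > 0:
                    img += rng.normal(0.0, noise.read_sigma, size=img.shape).astype(
                        np.float32
                    )
                stack[j, i] = np.maximum(img, 0.0)  # read-noise undershoot

    return RawStack(
        data=stack,
        lateral_pixel_nm=phantom.lateral_pixel_nm,
        axial_step_nm=phantom.axial_step_nm,
        wavelength_em_nm=otf.wavelength_em_nm,
        na=otf.na,
    ).validate()
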