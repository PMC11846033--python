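"""Core containers and validation shared by every reconstruction stage.

Conventions
-----------
* Raw acquisitions are indexed ``(angle, phase, z, y, x)`` — 3 angles, 5
  phases.  Readers translate instrument page orders into this canonical
  layout (see :mod:`spatialsim.io`).
* Coordinates are 0-based.  Frequency-domain arrays are DC-centered
  (``fftshift`` applied) unless a function documents otherwise.
* Pattern wavevectors are expressed in cycles per *raw* lateral pixel
  throughout, also on the 2x-upsampled reconstruction grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

N_ANGLES = 3
N_PHASES = 5

#: equally spaced default phase steps: 0, 2pi/5, ..., 8pi/5
DEFAULT_PHASE_STEPS = tuple(2.0 * np.pi * i / N_PHASES for i in range(N_PHASES))


class StackDimensionError(ValueError):
    """Raised when a raw stack does not have 3 angles x 5 phases x z,y,x."""


class StackValueError(ValueError):
    """Raised when a raw stack contains negative or non-finite pixels."""


class GridMismatchError(ValueError):
    """Raised when two volumes that must share a grid do not."""


@dataclass
class RawStack:
    """A raw 3D-SIM acquisition: 3 angles x 5 phases x (z, y, x) images.

    Pixel values are photon-count-like (non-negative, finite).  Integer TIFF
    data is converted to floating point on read with no rescaling.
    """

    data: np.ndarray
    lateral_pixel_nm: float
    axial_step_nm: float
    wavelength_em_nm: float
    na: float

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_z(self) -> int:
        return self.data.shape[2]

    @property
    def grid_yx(self) -> tuple[int, int]:
        return self.data.shape[3], self.data.shape[4]

    def widefield(self) -> np.ndarray:
        """Mean over all angles and phases: the conventional widefield volume."""
        return np.mean(self.data, axis=(0, 1), dtype=np.float64)

    def validate(self) -> "RawStack":
        return validate_stack(self)


def validate_stack(stack: RawStack) -> RawStack:
    """Check the raw-stack invariants, returning the stack unchanged.

    Raises
    ------
    StackDimensionError
        if the array is not 5-dimensional with exactly 3 angles and 5
        phases, or the lateral extents are not equal and even.
    StackValueError
        if any pixel is negative or non-finite (the first offending index
        is named in the message).
    """
    d = stack.data
    if d.ndim != 5:
        raise StackDimensionError(
            f"raw stack must be 5D (angle, phase, z, y, x); got {d.ndim}D"
        )
    if d.shape[0] != N_ANGLES or d.shape[1] != N_PHASES:
        raise StackDimensionError(
            f"raw stack must have {N_ANGLES} angles and {N_PHASES} phases; "
            f"got {d.shape[0]} angles, {d.shape[1]} phases"
        )
    if d.shape[2] < 1:
        raise StackDimensionError("raw stack needs at least one z layer")
    ny, nx = d.shape[3], d.shape[4]
    if ny != nx or ny % 2 != 0:
        raise StackDimensionError(
            f"lateral extents must be equal and even; got {ny} x {nx}"
        )
    bad = ~np.isfinite(d)
    if bad.any():
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise StackValueError(f"non-finite pixel at index {idx}")
    neg = d < 0
    if neg.any():
        idx = tuple(int(i) for i in np.argwhere(neg)[0])
        raise StackValueError(f"negative pixel at index {idx}")
    for name in ("lateral_pixel_nm", "axial_step_nm", "wavelength_em_nm", "na"):
        v = getattr(stack, name)
        if not np.isfinite(v) or v <= 0:
            raise StackValueError(f"{name} must be positive and finite; got {v}")
    return stack


@dataclass
class AngleParams:
    """Illumination parameters for one pattern orientation.

    ``wavevector`` is ``(ky, kx)`` in cycles per raw pixel; ``phase0`` is the
    pattern starting phase in radians.  ``a1``/``a2`` are the first/second
    order modulation depths, ``i0`` the intensity scale.
    """

    wavevector: tuple[float, float]
    phase0: float
    a1: float
    a2: float
    i0: float = 1.0

    def __post_init__(self) -> None:
        ky, kx = self.wavevector
        self.wavevector = (float(ky), float(kx))
        if not 0.0 <= self.a2 <= self.a1 <= 1.0:
            raise ValueError(
                f"modulation depths need 0 <= a2 <= a1 <= 1; got a1={self.a1}, a2={self.a2}"
            )
        if np.hypot(ky, kx) <= 0:
            raise ValueError("pattern wavevector must be non-zero")

    @property
    def magnitude(self) -> float:
        ky, kx = self.wavevector
        return float(np.hypot(ky, kx))


@dataclass
class IlluminationParams:
    """Per-angle pattern parameters plus the shared phase-step sequence."""

    angles: tuple[AngleParams, ...]
    phase_steps: tuple[float, ...] = DEFAULT_PHASE_STEPS

    def __post_init__(self) -> None:
        self.angles = tuple(self.angles)
        self.phase_steps = tuple(float(s) for s in self.phase_steps)
        if len(self.angles) != N_ANGLES:
            raise ValueError(f"need {N_ANGLES} angles; got {len(self.angles)}")
        if len(self.phase_steps) != N_PHASES:
            raise ValueError(f"need {N_PHASES} phase steps; got {len(self.phase_steps)}")

    def check_below_cutoff(self, cutoff_cycles_per_pixel: float) -> None:
        for j, a in enumerate(self.angles):
            if a.magnitude >= cutoff_cycles_per_pixel:
                raise ValueError(
                    f"angle {j}: |p|={a.magnitude:.4f} cycles/px is not below "
                    f"the detection cutoff {cutoff_cycles_per_pixel:.4f}"
                )


@dataclass
class OTFModel:
    """3D optical transfer function / point-spread function pair.

    ``otf`` is complex, DC-centered, normalized to 1 at DC; ``psf`` is real,
    non-negative and sums to 1.  The optics metadata is carried so filters
    can regenerate the OTF on derived (padded / upsampled) grids.
    """

    otf: np.ndarray
    psf: np.ndarray
    cutoff_lateral: float  # cycles / nm
    cutoff_axial: float  # cycles / nm
    na: float
    wavelength_em_nm: float
    lateral_pixel_nm: float
    axial_step_nm: float

    def cutoff_lateral_cpp(self) -> float:
        """Lateral detection cutoff in cycles per pixel."""
        return self.cutoff_lateral * self.lateral_pixel_nm


STAGES = ("SR0_minus", "SR1", "OS", "SR2", "WF", "SR_ref")


@dataclass
class SRVolume:
    """A reconstructed volume (z, y, x) on the 2x lateral grid.

    ``stage`` tags provenance: ``SR0_minus`` (spatial recombination, zero
    order removed), ``SR1`` (frequency-optimized), ``OS`` (HiLo optical
    section), ``SR2`` (final fusion), ``WF`` (widefield) or ``SR_ref``
    (frequency-domain reference reconstruction).
    """

    data: np.ndarray
    stage: str
    lateral_pixel_nm: float
    axial_step_nm: float

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.data.ndim != 3:
            raise ValueError(f"SRVolume data must be 3D (z, y, x); got {self.data.ndim}D")

    def with_stage(self, stage: str) -> "SRVolume":
        return replace(self, stage=stage)

    def require_same_grid(self, other: "SRVolume") -> None:
        if self.data.shape != other.data.shape:
            raise GridMismatchError(
                f"grids differ: {self.data.shape} vs {other.data.shape}"
            )
        if not np.isclose(self.lateral_pixel_nm, other.lateral_pixel_nm) or not np.isclose(
            self.axial_step_nm, other.axial_step_nm
        ):
            raise GridMismatchError("pixel metadata differs between volumes")


@dataclass
class FilterBank:
    """Parameters of the frequency-optimization and HiLo filters.

    All frequency parameters are in cycles per raw pixel.  ``None`` disables
    the corresponding filter (identity configuration).
    """

    lo_sigma: float | None = None  # HiLo Lo Gaussian sigma; None -> |p|/4 rule
    notch_width: float = 0.01
    notch_depth: float = 0.95
    # "auto" -> 2.4x widefield lateral cutoff; None -> apodization off
    apodization_cutoff: float | str | None = "auto"
    wiener_w: float | None = 0.1
    twostep_suppression: float = 1.0  # out-of-band suppression in [0, 1]
    twostep_rolloff: float | None = None  # Gaussian rolloff sigma; None -> off
    # low-pass input of the optical section: "amplitude" (demodulated
    # first-harmonic magnitude; sections smooth backgrounds) or "literal"
    # (raw first-phase image; exact widefield limit)
    hilo_mode: str = "amplitude"

    def __post_init__(self) -> None:
        if not 0.0 <= self.notch_depth <= 1.0:
            raise ValueError(f"notch_depth must be in [0, 1]; got {self.notch_depth}")
        if not 0.0 <= self.twostep_suppression <= 1.0:
            raise ValueError(
                f"twostep_suppression must be in [0, 1]; got {self.twostep_suppression}"
            )
        if self.wiener_w is not None and self.wiener_w <= 0:
            raise ValueError(f"wiener_w must be positive; got {self.wiener_w}")
        if self.hilo_mode not in ("amplitude", "literal"):
            raise ValueError(f"hilo_mode must be 'amplitude' or 'literal'; got {self.hilo_mode}")

    @classmethod
    def identity(cls) -> "FilterBank":
        """A configuration under which `optimize` reproduces its input."""
        return cls(notch_depth=0.0, apodization_cutoff=None, wiener_w=None,
                   twostep_suppression=0.0, twostep_rolloff=None)
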