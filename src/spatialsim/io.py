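"""Readers/writers for raw and reconstructed stacks, parameter files and
configuration.

Raw acquisitions are multi-page TIFFs whose page count is divisible by 15
(3 angles x 5 phases per z plane).  Instrument dialects order pages
differently; the declared ``layout`` token (e.g. ``"PAZ"`` = phase fastest,
then angle, then z) maps pages into the canonical ``(angle, phase, z, y,
x)`` order — the mapping is declared, never sniffed.  Optical metadata
travels in a plain-text sidecar (``<path>.meta``).
"""

from __future__ import annotations

import configparser
import json
from pathlib import Path

import numpy as np
import tifffile

from .datamodel import (
    AngleParams,
    IlluminationParams,
    RawStack,
    SRVolume,
    N_ANGLES,
    N_PHASES,
    validate_stack,
)

_AXIS_SIZES = {"P": N_PHASES, "A": N_ANGLES}
LAYOUTS = ("PAZ", "APZ", "ZAP", "PZA", "AZP", "ZPA")


def _page_index_map(layout: str, nz: int) -> np.ndarray:
    """page number for each canonical (angle, phase, z) triple."""
    if sorted(layout) != ["A", "P", "Z"]:
        raise ValueError(f"unknown layout token {layout!r}; expected a permutation of 'PAZ'")
    sizes = {"P": N_PHASES, "A": N_ANGLES, "Z": nz}
    stride = {}
    s = 1
    for axis in layout:  # first letter varies fastest
        stride[axis] = s
        s *= sizes[axis]
    a = np.arange(N_ANGLES)[:, None, None]
    p = np.arange(N_PHASES)[None, :, None]
    z = np.arange(nz)[None, None, :]
    return a * stride["A"] + p * stride["P"] + z * stride["Z"]


def _meta_path(path) -> Path:
    return Path(str(path) + ".meta")


def write_raw(path, stack: RawStack, layout: str = "PAZ") -> None:
    """Write a raw stack as a multi-page TIFF plus a plain-text metadata
    sidecar; pages ordered per ``layout``."""
    validate_stack(stack)
    nz = stack.n_z
    index = _page_index_map(layout, nz)
    n_pages = N_ANGLES * N_PHASES * nz
    pages = [None] * n_pages
    for a in range(N_ANGLES):
        for p in range(N_PHASES):
            for z in range(nz):
                pages[int(index[a, p, z])] = stack.data[a, p, z]
    tifffile.imwrite(str(path), np.stack(pages))
    cfg = configparser.ConfigParser()
    cfg["stack"] = {
        "layout": layout,
        "lateral_pixel_nm": repr(stack.lateral_pixel_nm),
        "axial_step_nm": repr(stack.axial_step_nm),
        "wavelength_em_nm": repr(stack.wavelength_em_nm),
        "na": repr(stack.na),
    }
    with open(_meta_path(path), "w") as fh:
        cfg.write(fh)


def read_raw(
    path,
    layout: str | None = None,
    *,
    page_order: np.ndarray | None = None,
    lateral_pixel_nm: float | None = None,
    axial_step_nm: float | None = None,
    wavelength_em_nm: float | None = None,
    na: float | None = None,
) -> RawStack:
    """Read a multi-page TIFF into a canonical raw stack.

    ``layout`` declares the page order (permutation of ``"PAZ"``, first
    letter fastest) or ``"explicit"`` with a ``page_order`` array of shape
    (3, 5, z) giving the page number of each (angle, phase, z).  Metadata
    defaults come from the ``<path>.meta`` sidecar; keyword arguments
    override it.  Integer pixel data is converted to float32 with no
    rescaling.
    """
    pages = tifffile.imread(str(path))
    if pages.ndim == 2:
        pages = pages[None]
    n_pages = pages.shape[0]
    if n_pages % (N_ANGLES * N_PHASES) != 0:
        raise ValueError(f"pages ({n_pages}) not divisible by {N_ANGLES * N_PHASES}")
    nz = n_pages // (N_ANGLES * N_PHASES)

    meta: dict[str, float | str] = {}
    mp = _meta_path(path)
    if mp.exists():
        cfg = configparser.ConfigParser()
        cfg.read(mp)
        if "stack" in cfg:
            meta = dict(cfg["stack"])
    if layout is None:
        layout = str(meta.get("layout", "PAZ"))

    def pick(name: str, override):
        if override is not None:
            return float(override)
        if name in meta:
            return float(meta[name])
        raise ValueError(f"missing metadata {name!r}: no sidecar entry and no override")

    if layout == "explicit":
        if page_order is None:
            raise ValueError("layout='explicit' requires page_order")
        index = np.asarray(page_order)
        if index.shape != (N_ANGLES, N_PHASES, nz):
            raise ValueError(
                f"page_order shape {index.shape} != {(N_ANGLES, N_PHASES, nz)}"
            )
    else:
        index = _page_index_map(layout, nz)

    if np.issubdtype(pages.dtype, np.integer):
        pages = pages.astype(np.float32)
    data = pages[index]  # (angle, phase, z, y, x)
    return validate_stack(
        RawStack(
            data=data,
            lateral_pixel_nm=pick("lateral_pixel_nm", lateral_pixel_nm),
            axial_step_nm=pick("axial_step_nm", axial_step_nm),
            wavelength_em_nm=pick("wavelength_em_nm", wavelength_em_nm),
            na=pick("na", na),
        )
    )


def write_volume(path, volume: SRVolume, *, dtype: str = "float32") -> None:
    """Export a reconstructed volume as a z-stack TIFF (one page per plane).

    ``dtype="float32"`` (default) writes raw values; ``"uint16"`` applies
    min-max scaling recorded in the sidecar.
    """
    data = volume.data
    scale_meta = {}
    if dtype == "uint16":
        lo, hi = float(data.min()), float(data.max())
        scale = 65535.0 / (hi - lo) if hi > lo else 1.0
        data = ((data - lo) * scale).astype(np.uint16)
        scale_meta = {"scale_min": repr(lo), "scale_max": repr(hi)}
    elif dtype == "float32":
        data = data.astype(np.float32)
    else:
        raise ValueError(f"unsupported export dtype {dtype!r}")
    tifffile.imwrite(str(path), data)
    cfg = configparser.ConfigParser()
    cfg["volume"] = {
        "stage": volume.stage,
        "lateral_pixel_nm": repr(volume.lateral_pixel_nm),
        "axial_step_nm": repr(volume.axial_step_nm),
        **scale_meta,
    }
    with open(_meta_path(path), "w") as fh:
        cfg.write(fh)


def read_volume(path) -> SRVolume:
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    cfg = configparser.ConfigParser()
    cfg.read(_meta_path(path))
    sec = cfg["volume"]
    return SRVolume(
        data=np.asarray(data),
        stage=sec.get("stage", "SR2"),
        lateral_pixel_nm=float(sec["lateral_pixel_nm"]),
        axial_step_nm=float(sec["axial_step_nm"]),
    )


def save_params(path, params: IlluminationParams) -> None:
    """Serialize illumination parameters to a plain-text file, one block
    per angle (p_y, p_x, phase0, a1, a2, i0)."""
    cfg = configparser.ConfigParser()
    cfg["global"] = {"phase_steps": " ".join(repr(s) for s in params.phase_steps)}
    for j, a in enumerate(params.angles):
        cfg[f"angle{j}"] = {
            "p_y": repr(a.wavevector[0]),
            "p_x": repr(a.wavevector[1]),
            "phase0": repr(a.phase0),
            "a1": repr(a.a1),
            "a2": repr(a.a2),
            "i0": repr(a.i0),
        }
    with open(path, "w") as fh:
        cfg.write(fh)


def load_params(path) -> IlluminationParams:
    cfg = configparser.ConfigParser()
    if not cfg.read(path):
        raise FileNotFoundError(path)
    steps = tuple(float(s) for s in cfg["global"]["phase_steps"].split())
    angles = []
    for j in range(N_ANGLES):
        sec = cfg[f"angle{j}"]
        angles.append(
            AngleParams(
                wavevector=(float(sec["p_y"]), float(sec["p_x"])),
                phase0=float(sec["phase0"]),
                a1=float(sec["a1"]),
                a2=float(sec["a2"]),
                i0=float(sec.get("i0", "1.0")),
            )
        )
    return IlluminationParams(angles=tuple(angles), phase_steps=steps)


def write_report(path, report: dict) -> None:
    """Machine-readable run report next to the outputs."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
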