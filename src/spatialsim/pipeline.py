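"""End-to-end reconstruction pipeline and run reporting.

Stages: (optional) parameter estimation -> zero-order removal + spatial
recombination -> frequency optimization -> HiLo optical section -> fusion.
Per-stage wall time and energy (sum of squares) are logged to stderr and
collected in a machine-readable report.  Deterministic for fixed inputs.
"""

from __future__ import annotations

import logging
import time

import numpy as np

from ._fft import upsample_lateral
from .datamodel import FilterBank, IlluminationParams, OTFModel, RawStack, SRVolume
from .fuse import fuse, spectral_matching_weight
from .freqopt import optimize
from .hilo import optical_section
from .oracle import reconstruct_reference
from .params import estimate_illumination
from .spatial import recombine_spatial

log = logging.getLogger("spatialsim")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and context."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _run_stage(name: str, fn, report: dict):
    t0 = time.perf_counter()
    try:
        result = fn()
    except Exception as exc:  # noqa: BLE001 - stage context is the contract
        raise StageError(name, exc) from exc
    dt = time.perf_counter() - t0
    entry: dict = {"seconds": round(dt, 3)}
    if isinstance(result, SRVolume):
        entry["energy"] = float(np.sum(np.square(result.data, dtype=np.float64)))
    report.setdefault("stages", {})[name] = entry
    log.info("stage %-16s %7.2f s", name, dt)
    return result


def run_pipeline(
    stack: RawStack,
    params: IlluminationParams | None = None,
    otf: OTFModel | None = None,
    filters: FilterBank | None = None,
    *,
    engine: str = "spatial",
    os_only: bool = False,
    os_weight: float | None = None,
    upsample: int = 2,
) -> tuple[dict[str, SRVolume], dict]:
    """Run the full reconstruction on a validated raw stack.

    Returns ``(volumes, report)``.  ``volumes`` maps stage names to
    :class:`SRVolume`: ``WF``, ``OS`` (and, unless ``os_only``,
    ``SR0_minus``, ``SR1`` and ``SR2`` for the spatial engine or ``SR_ref``
    for the reference engine).  ``params=None`` triggers estimation from
    the data; ``otf``/``filters`` default to the metadata optics and the
    default filter bank.
    """
    from .simulator import make_otf3d

    report: dict = {"engine": engine, "os_only": os_only}
    stack.validate()
    nz, ny, nx = stack.data.shape[2:]

    if otf is None:
        otf = make_otf3d(
            stack.na, stack.wavelength_em_nm, stack.lateral_pixel_nm,
            stack.axial_step_nm, (nz, ny, nx),
        )
    if filters is None:
        filters = FilterBank()
    if params is None:
        params = _run_stage("estimate", lambda: estimate_illumination(stack), report)
    report["params"] = {
        f"angle{j}": {
            "p_y": a.wavevector[0], "p_x": a.wavevector[1],
            "phase0": a.phase0, "a1": a.a1, "a2": a.a2,
        }
        for j, a in enumerate(params.angles)
    }
    report["filters"] = {
        "notch_width": filters.notch_width,
        "notch_depth": filters.notch_depth,
        "apodization_cutoff": filters.apodization_cutoff,
        "wiener_w": filters.wiener_w,
        "lo_sigma": filters.lo_sigma,
        "twostep_suppression": filters.twostep_suppression,
    }

    volumes: dict[str, SRVolume] = {}
    big = stack.data.size > 60_000_000
    wf = _run_stage(
        "widefield",
        lambda: SRVolume(
            data=upsample_lateral(stack.widefield(), upsample).astype(
                np.float32 if big else np.float64
            ),
            stage="WF",
            lateral_pixel_nm=stack.lateral_pixel_nm / upsample,
            axial_step_nm=stack.axial_step_nm,
        ),
        report,
    )
    volumes["WF"] = wf

    volumes["OS"] = _run_stage(
        "optical_section", lambda: optical_section(stack, filters, params, upsample=upsample),
        report,
    )
    if os_only:
        return volumes, report

    if engine == "spatial":
        sr0 = _run_stage(
            "recombine", lambda: recombine_spatial(stack, params, upsample=upsample), report
        )
        volumes["SR0_minus"] = sr0
        sr1 = _run_stage(
            "optimize", lambda: optimize(sr0, params, otf, filters, upsample=upsample), report
        )
        volumes["SR1"] = sr1
        weight = os_weight
        if weight is None:
            weight = spectral_matching_weight(sr1, volumes["OS"])
        report["os_weight"] = weight
        volumes["SR2"] = _run_stage(
            "fuse", lambda: fuse(sr1, volumes["OS"], weight), report
        )
    elif engine == "reference":
        volumes["SR_ref"] = _run_stage(
            "reference",
            lambda: reconstruct_reference(
                stack, params, otf,
                wiener_w=filters.wiener_w if filters.wiener_w is not None else 0.05,
                include_zero_order=True, upsample=upsample,
            ),
            report,
        )
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return volumes, report
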