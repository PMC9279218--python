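"""End-to-end case processing: raw phases in, FD map and sizes out.

Stage order follows the analysis workflow: rigid phase alignment →
isotropic resampling → noise-adaptive denoising → portal-vein intensity
normalization → phase-baseline removal → local FD mapping → (optional)
FD-threshold segmentation → size measurement.  Every stage's parameters
are logged into a provenance record embedding the configuration hash, and
reruns with identical inputs and configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._version import __version__
from .fractal import DEFAULT_LOCAL_SCALES, DEFAULT_WINDOW_RADIUS, FDMap, local_fd_map
from .io import config_hash, read_mask, read_stack, write_measurements_csv, write_volume
from .measure import SizeMeasurement, measure_mask, segment_fd_threshold
from .preprocess import (
    PreprocessConfig,
    align_phases,
    denoise,
    estimate_noise,
    measure_reference_signals,
    normalize_enhancement,
    remove_phase_baseline,
    resample_isotropic,
    resample_mask,
)
from .types import DEFAULT_PHASE_LABELS, PhaseStack, RegionMask


@dataclass
class CaseBundle:
    """File-based description of one case's inputs."""

    case_id: str
    phase_paths: Sequence[str | Path]
    phase_labels: Sequence[str] = DEFAULT_PHASE_LABELS
    muscle_mask_path: str | Path | None = None
    portal_vein_mask_path: str | Path | None = None

    def load(self) -> tuple[PhaseStack, RegionMask | None, RegionMask | None]:
        stack = read_stack(self.phase_paths, self.phase_labels)
        muscle = (
            read_mask(self.muscle_mask_path, "muscle") if self.muscle_mask_path else None
        )
        vein = (
            read_mask(self.portal_vein_mask_path, "portal_vein")
            if self.portal_vein_mask_path
            else None
        )
        return stack, muscle, vein


@dataclass
class PipelineResult:
    """Everything one case run produces."""

    fd_map: FDMap
    stack: PhaseStack
    segmentation: RegionMask | None
    measurement: SizeMeasurement | None
    provenance: dict = field(default_factory=dict)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    stack: PhaseStack,
    muscle_roi: RegionMask | None,
    portal_vein_roi: RegionMask | None,
    config: PreprocessConfig | None = None,
    *,
    case_id: str = "case",
    segment_threshold: float | None = None,
    seed_point: tuple[int, int, int] | None = None,
    window_radius: int = DEFAULT_WINDOW_RADIUS,
    scales: Sequence[int] = DEFAULT_LOCAL_SCALES,
) -> PipelineResult:
    """Run the full analysis chain on an in-memory case.

    ``muscle_roi``/``portal_vein_roi`` may be None, in which case the
    denoising uses a zero noise estimate (bilateral step skipped) and the
    intensity normalization is skipped, respectively.  Segmentation runs
    only when both ``segment_threshold`` and ``seed_point`` are given.
    """
    config = config or PreprocessConfig()
    provenance: dict = {
        "case_id": case_id,
        "version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": config_hash(config),
        "stages": [],
    }

    def stage(name, fn, *args, **kw):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kw)
        except Exception as exc:  # annotate failures with the stage name
            raise StageError(name, exc) from exc
        provenance["stages"].append({"name": name, "seconds": round(time.perf_counter() - t0, 3)})
        return out

    aligned, shift_reports = stage("align", align_phases, stack, 0, config)
    provenance["shifts"] = [dataclasses.asdict(r) for r in shift_reports]

    resampled = stage("resample", resample_isotropic, aligned, config.target_spacing_mm, config)
    if muscle_roi is not None:
        muscle_roi = resample_mask(muscle_roi, config.target_spacing_mm)
        noise = stage("estimate_noise", estimate_noise, resampled, muscle_roi, 0)
    else:
        from .preprocess import NoiseEstimate

        noise = NoiseEstimate(sd_hu=0.0, roi_voxel_count=2)
    provenance["noise_sd_hu"] = noise.sd_hu

    denoised = stage("denoise", denoise, resampled, noise, config)

    if portal_vein_roi is not None:
        portal_vein_roi = resample_mask(portal_vein_roi, config.target_spacing_mm)
        refs = stage("reference_signals", measure_reference_signals, denoised, portal_vein_roi)
        normalized = stage("normalize", normalize_enhancement, denoised, refs)
        provenance["reference_signals"] = {"i0": refs.i0, "ipv": dict(refs.ipv_per_phase)}
    else:
        normalized = denoised

    detrended = stage("phase_baseline", remove_phase_baseline, normalized)
    fd_map = stage("local_fd_map", local_fd_map, detrended, window_radius, scales)

    segmentation = None
    measurement = None
    if segment_threshold is not None and seed_point is not None:
        segmentation = stage("segment", segment_fd_threshold, fd_map, segment_threshold, seed_point)
        measurement = stage("measure", measure_mask, segmentation)

    return PipelineResult(
        fd_map=fd_map,
        stack=detrended,
        segmentation=segmentation,
        measurement=measurement,
        provenance=provenance,
    )


def write_result(result: PipelineResult, directory: str | Path) -> dict[str, Path]:
    """Write FD map (NIfTI) and measurement CSV; returns output paths."""
    directory = Path(directory)
    out: dict[str, Path] = {}
    fd_path = directory / "fd_map.nii.gz"
    write_volume(result.fd_map.values, result.fd_map.spacing, fd_path)
    out["fd_map"] = fd_path
    if result.measurement is not None:
        csv_path = directory / "measurements.csv"
        m = result.measurement
        write_measurements_csv(
            [
                {
                    "case_id": result.provenance["case_id"],
                    "method": f"fd_map[{result.provenance['config_hash']}]",
                    "label": "fd_segmentation",
                    "volume_ml": m.volume_ml,
                    "feret_mm": m.feret_mm,
                    "recist_mm": m.recist_mm,
                    "voxel_count": m.voxel_count,
                }
            ],
            csv_path,
        )
        out["measurements"] = csv_path
    return out
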