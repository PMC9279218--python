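"""NIfTI volume I/O, JSON configuration, and CSV reports.

Volumes are NIfTI-1 (.nii / .nii.gz) with spacing taken from the header
zooms; the affine is a plain diagonal scaling (no origin or orientation
handling — all grids are assumed co-registered, axis-aligned and 0-based,
matching the package's index-times-spacing world convention).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .preprocess import PreprocessConfig
from .types import PhaseStack, RegionMask


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a 3D NIfTI volume; returns (array, spacing_mm)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def write_volume(
    grid: np.ndarray, spacing: Sequence[float], path: str | Path, dtype=np.float32
) -> None:
    """Write a 3D volume as NIfTI-1 with a diagonal-spacing affine."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"output directory {path.parent} does not exist")
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(grid, dtype=dtype), affine)
    img.header.set_zooms(tuple(float(s) for s in spacing))
    nib.save(img, str(path))


def read_stack(
    phase_paths: Sequence[str | Path],
    phase_labels: Sequence[str],
) -> PhaseStack:
    """Assemble a PhaseStack from one NIfTI file per phase (same grid)."""
    if len(phase_paths) != len(phase_labels):
        raise ValueError("one path per phase label required")
    volumes, spacings = zip(*(read_volume(p) for p in phase_paths))
    shapes = {v.shape for v in volumes}
    if len(shapes) > 1:
        raise ValueError(f"phases have mismatched grids: {sorted(shapes)}")
    if any(not np.allclose(s, spacings[0], atol=1e-4) for s in spacings):
        raise ValueError(f"phases have mismatched spacings: {spacings}")
    return PhaseStack(
        voxels=np.stack(volumes, axis=-1),
        spacing=spacings[0],
        phase_labels=tuple(phase_labels),
    )


def write_stack(stack: PhaseStack, directory: str | Path, prefix: str = "phase") -> list[Path]:
    """Write each phase as ``<prefix>_<label>.nii.gz``; returns the paths."""
    directory = Path(directory)
    paths = []
    for p, label in enumerate(stack.phase_labels):
        out = directory / f"{prefix}_{label}.nii.gz"
        write_volume(stack.voxels[..., p], stack.spacing, out)
        paths.append(out)
    return paths


def read_mask(path: str | Path, label: str = "") -> RegionMask:
    data, spacing = read_volume(path)
    name = Path(path).name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
            break
    return RegionMask(data > 0.5, spacing, label or name)


def write_mask(mask: RegionMask, path: str | Path) -> None:
    write_volume(mask.voxels.astype(np.uint8), mask.spacing, path, dtype=np.uint8)


def load_config(path: str | Path | None) -> PreprocessConfig:
    """PreprocessConfig from a JSON file (missing keys keep defaults)."""
    if path is None:
        return PreprocessConfig()
    with open(path) as fh:
        raw = json.load(fh)
    known = {f.name for f in dataclasses.fields(PreprocessConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PreprocessConfig(**raw)


def config_hash(config: PreprocessConfig) -> str:
    """Short stable hash of a configuration, embedded in outputs."""
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_measurements_csv(rows: list[dict], path: str | Path) -> None:
    """Append-style measurement report with a fixed column order."""
    columns = ["case_id", "method", "label", "volume_ml", "feret_mm", "recist_mm", "voxel_count"]
    df = pd.DataFrame(rows)
    for c in columns:
        if c not in df.columns:
            df[c] = np.nan
    df[columns].to_csv(path, index=False, float_format="%.6f")
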