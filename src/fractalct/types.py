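"""Shared containers for multiphasic CT volumes, masks and derived maps.

Axis convention: 4D arrays are indexed ``(x, y, z, phase)``; 3D arrays and
masks are ``(x, y, z)`` on the same spatial grid.  World coordinates are
``index * spacing`` in millimetres (0-based voxel centres, no origin or
orientation handling) — masks must share the stack grid exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Canonical acquisition order of the contrast-enhancement phases.
DEFAULT_PHASE_LABELS = ("unenhanced", "parenchymal", "portal_venous")


@dataclass
class PhaseStack:
    """A co-registered multiphasic CT volume.

    Parameters
    ----------
    voxels
        4D array ``(x, y, z, phase)``.  Hounsfield units before intensity
        normalization, dimensionless normalized units (portal vein == 100)
        afterwards.
    spacing
        Voxel spacing ``(sx, sy, sz)`` in mm, all positive.
    phase_labels
        Ordered phase names, one per entry of the last axis.
    normalized
        True once portal-vein intensity normalization has been applied.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    phase_labels: tuple[str, ...] = DEFAULT_PHASE_LABELS
    normalized: bool = False

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 4:
            raise ValueError(f"voxels must be 4D (x,y,z,phase), got {self.voxels.ndim}D")
        if self.voxels.shape[3] < 2:
            raise ValueError("a PhaseStack needs at least 2 phases")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        self.phase_labels = tuple(self.phase_labels)
        if len(self.phase_labels) != self.voxels.shape[3]:
            raise ValueError("phase_labels must match the number of phases")

    @property
    def n_phases(self) -> int:
        return self.voxels.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]

    def phase_index(self, label: str) -> int:
        try:
            return self.phase_labels.index(label)
        except ValueError:
            raise KeyError(f"no phase labelled {label!r}; have {self.phase_labels}") from None

    def phase(self, key: int | str) -> np.ndarray:
        """Return one 3D phase volume (view)."""
        idx = key if isinstance(key, int) else self.phase_index(key)
        return self.voxels[..., idx]

    def with_voxels(self, voxels: np.ndarray, **changes) -> "PhaseStack":
        """Copy of this stack with new voxel data (and optional field changes)."""
        return replace(self, voxels=voxels, **changes)


@dataclass
class RegionMask:
    """Binary voxel mask on a stack's spatial grid.

    ``label`` names the anatomical region (core, rim, tumour, pancreas,
    portal_vein, muscle, ...).  Empty masks are allowed; operations that
    require voxels raise explicitly.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    label: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError(f"mask must be 3D, got {self.voxels.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    def indices_mm(self) -> np.ndarray:
        """(n, 3) array of voxel-centre world coordinates in mm."""
        idx = np.argwhere(self.voxels)
        return idx * np.asarray(self.spacing)


def check_same_grid(stack: PhaseStack, mask: RegionMask, *, what: str = "mask") -> None:
    """Raise if a mask does not share the stack's spatial grid."""
    if mask.voxels.shape != stack.spatial_shape:
        raise ValueError(
            f"{what} shape {mask.voxels.shape} does not match stack grid {stack.spatial_shape}"
        )
    if not np.allclose(mask.spacing, stack.spacing, atol=1e-4):
        raise ValueError(f"{what} spacing {mask.spacing} does not match stack {stack.spacing}")
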