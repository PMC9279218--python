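"""Tumour size measurement and FD-threshold segmentation.

Size conventions: distances are between voxel centres in world
coordinates (``index × spacing``, mm), so a single voxel has diameter 0 —
users expecting full-extent diameters can add one voxel.  Volume is the
exact voxel count times the voxel volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .fractal import FDMap
from .types import RegionMask


@dataclass
class SizeMeasurement:
    """Volume and diameters of one segmentation."""

    volume_ml: float
    feret_mm: float
    recist_mm: float
    voxel_count: int


def volume_ml(mask: RegionMask) -> float:
    """Segmented volume in mL: ``voxel_count × sx·sy·sz / 1000`` (exact)."""
    sx, sy, sz = mask.spacing
    return mask.voxel_count * sx * sy * sz / 1000.0


def _max_pairwise_distance(points: np.ndarray) -> float:
    """Maximum Euclidean pairwise distance, via the convex hull when the
    point cloud is full-dimensional (the diameter is attained on hull
    vertices), otherwise brute force."""
    if len(points) < 2:
        return 0.0
    if len(points) > points.shape[1] + 1:
        try:
            hull = ConvexHull(points)
            points = points[hull.vertices]
        except QhullError:
            pass  # degenerate (flat) cloud: fall through to brute force
    return float(pdist(points).max())


def feret_diameter_3d(mask: RegionMask) -> float:
    """Maximum 3D caliper (Feret) diameter in mm.

    The maximum tumour extent independent of spatial alignment or axis
    orientation: the largest voxel-centre distance in the mask, computed
    on the convex hull vertices.
    """
    if mask.voxel_count == 0:
        raise ValueError("Feret diameter of an empty mask is undefined")
    return _max_pairwise_distance(mask.indices_mm())


def recist_diameter(mask: RegionMask) -> float:
    """Largest in-plane (axial, i.e. fixed-z) diameter in mm.

    The response-evaluation convention measures within standard planes;
    this is the maximum over axial slices of the in-slice maximum
    voxel-centre distance.  Always ≤ the 3D Feret diameter.
    """
    if mask.voxel_count == 0:
        raise ValueError("RECIST diameter of an empty mask is undefined")
    sx, sy, _ = mask.spacing
    best = 0.0
    for z in range(mask.voxels.shape[2]):
        idx = np.argwhere(mask.voxels[:, :, z])
        if len(idx) < 2:
            continue
        best = max(best, _max_pairwise_distance(idx * np.array([sx, sy])))
    return best


def measure_mask(mask: RegionMask) -> SizeMeasurement:
    """All size measurements for one segmentation."""
    if mask.voxel_count == 0:
        return SizeMeasurement(0.0, 0.0, 0.0, 0)
    return SizeMeasurement(
        volume_ml=volume_ml(mask),
        feret_mm=feret_diameter_3d(mask),
        recist_mm=recist_diameter(mask),
        voxel_count=mask.voxel_count,
    )


#: 26-connectivity structuring element (permissive: suits thin rims).
_CONN26 = np.ones((3, 3, 3), dtype=bool)


def segment_fd_threshold(
    fdmap: FDMap, threshold: float, seed_point: tuple[int, int, int]
) -> RegionMask:
    """Region-grow a tumour mask from an FD map.

    Returns the 26-connected component of ``{FD ≥ threshold}`` containing
    ``seed_point`` (empty if the seed itself is below threshold).  Raising
    the threshold never grows the mask.
    """
    seed = tuple(int(i) for i in seed_point)
    shape = fdmap.values.shape
    if len(seed) != 3 or any(i < 0 or i >= n for i, n in zip(seed, shape)):
        raise IndexError(f"seed point {seed} outside grid {shape}")
    above = fdmap.values >= threshold
    if not above[seed]:
        return RegionMask(np.zeros(shape, bool), fdmap.spacing, "fd_segmentation")
    labels, _ = ndimage.label(above, structure=_CONN26)
    return RegionMask(labels == labels[seed], fdmap.spacing, "fd_segmentation")
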