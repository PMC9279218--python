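"""Standardisation of raw multiphasic CT before fractal analysis.

Four steps, in pipeline order:

1. ``align_phases`` — rigid integer-voxel alignment of the phases by
   cross-correlation (a fallback for externally registered data; full
   deformable registration is out of scope and assumed done upstream).
2. ``resample_isotropic`` — linear resampling of every phase to a common
   isotropic voxel spacing (default 0.7 mm), preserving physical extent.
3. ``denoise`` — noise-adaptive scheme: a 3D median filter (radius 2
   voxels) followed by a 3D bilateral filter (spatial parameter 1 voxel,
   photometric range parameter tied to the image noise measured in an
   erector-muscle ROI).
4. ``normalize_enhancement`` — portal-vein intensity normalization,
   ``I = (I_voxel − I₀) / (I_pv − I₀) × 100``, mapping unenhanced
   portal-vein blood to 0 and contrast-phase portal-vein blood to 100 so
   that circulation differences between patients cancel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .types import PhaseStack, RegionMask, check_same_grid

PORTAL_PHASE = "portal_venous"
UNENHANCED_PHASE = "unenhanced"


@dataclass
class PreprocessConfig:
    """Tunable pre-processing parameters (units noted per field)."""

    target_spacing_mm: float = 0.7
    median_radius: int = 2  # voxels
    bilateral_distance: int = 1  # voxels
    bilateral_range_factor: float = 2.0  # range sigma = factor * noise SD
    shift_search_radius: int = 10  # voxels
    #: minimum normalized correlation for a confident shift estimate
    alignment_confidence: float = 0.3


@dataclass
class NoiseEstimate:
    """Image-noise level measured in a homogeneous muscle ROI."""

    sd_hu: float
    roi_voxel_count: int

    def __post_init__(self) -> None:
        if self.sd_hu < 0:
            raise ValueError("noise SD cannot be negative")
        if self.roi_voxel_count < 2:
            raise ValueError("noise ROI needs at least 2 voxels")


@dataclass
class ReferenceSignals:
    """Portal-vein reference intensities for normalization.

    ``i0`` is the unenhanced portal-vein signal (HU); ``ipv_per_phase``
    maps each contrast-phase label to its portal-vein signal (HU).
    """

    i0: float
    ipv_per_phase: Mapping[str, float]

    def __post_init__(self) -> None:
        for label, ipv in self.ipv_per_phase.items():
            if ipv == self.i0:
                raise ValueError(
                    f"portal-vein signal in phase {label!r} equals the unenhanced "
                    "signal; normalization denominator would vanish"
                )


@dataclass
class ShiftReport:
    """Alignment result for one phase relative to the reference phase."""

    phase_label: str
    shift: tuple[int, int, int]
    score: float
    low_confidence: bool


def resample_isotropic(
    stack: PhaseStack, target_mm: float | None = None, config: PreprocessConfig | None = None
) -> PhaseStack:
    """Resample every phase to isotropic ``target_mm`` spacing (linear).

    The physical extent is preserved within one voxel: the new grid has
    ``round(n · s / target)`` voxels per axis and world coordinates
    ``index · target``, sampled from the input by trilinear interpolation
    (edge values extended beyond the boundary).
    """
    config = config or PreprocessConfig()
    target = float(target_mm if target_mm is not None else config.target_spacing_mm)
    if target <= 0:
        raise ValueError("target spacing must be positive")
    if any(n == 0 for n in stack.voxels.shape):
        raise ValueError("empty grid")

    factors = np.array([s / target for s in stack.spacing])
    if np.allclose(factors, 1.0, rtol=0, atol=1e-6):
        return stack.with_voxels(stack.voxels.copy(), spacing=(target,) * 3)

    new_shape = tuple(max(1, int(round(n * f))) for n, f in zip(stack.spatial_shape, factors))
    matrix = np.diag([target / s for s in stack.spacing])
    out = np.empty(new_shape + (stack.n_phases,), dtype=np.float64)
    for p in range(stack.n_phases):
        out[..., p] = ndimage.affine_transform(
            stack.voxels[..., p],
            matrix,
            output_shape=new_shape,
            order=1,
            mode="nearest",
        )
    return stack.with_voxels(out, spacing=(target,) * 3)


def resample_mask(mask: RegionMask, target_mm: float) -> RegionMask:
    """Nearest-neighbour resampling of a label mask (no invented labels)."""
    if target_mm <= 0:
        raise ValueError("target spacing must be positive")
    factors = np.array([s / target_mm for s in mask.spacing])
    if np.allclose(factors, 1.0, rtol=0, atol=1e-6):
        return RegionMask(mask.voxels.copy(), (target_mm,) * 3, mask.label)
    new_shape = tuple(max(1, int(round(n * f))) for n, f in zip(mask.voxels.shape, factors))
    matrix = np.diag([target_mm / s for s in mask.spacing])
    out = ndimage.affine_transform(
        mask.voxels.astype(np.float32),
        matrix,
        output_shape=new_shape,
        order=0,
        mode="nearest",
    )
    return RegionMask(out > 0.5, (target_mm,) * 3, mask.label)


def estimate_noise(stack: PhaseStack, muscle_roi: RegionMask, phase: int | str = 0) -> NoiseEstimate:
    """Sample SD of the muscle-ROI voxels in one phase (ddof = 1)."""
    check_same_grid(stack, muscle_roi, what="muscle ROI")
    values = stack.phase(phase)[muscle_roi.voxels]
    if values.size < 2:
        raise ValueError("noise ROI must contain at least 2 voxels")
    return NoiseEstimate(sd_hu=float(values.std(ddof=1)), roi_voxel_count=int(values.size))


def _ball_footprint(radius: int) -> np.ndarray:
    r = int(radius)
    grids = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (grids**2).sum(axis=0) <= r * r


def _bilateral3d(volume: np.ndarray, spatial_radius: int, range_sigma: float) -> np.ndarray:
    """Brute-force 3D bilateral filter over a small Chebyshev window.

    Suited to the radius-1 window used here (27 offsets); spatial weights
    are Gaussian with sigma equal to the window radius, photometric
    weights Gaussian with ``range_sigma``.  Mirror boundary.
    """
    r = int(spatial_radius)
    padded = np.pad(volume, r, mode="reflect")
    num = np.zeros_like(volume)
    den = np.zeros_like(volume)
    nx, ny, nz = volume.shape
    for dx in range(-r, r + 1):
        for dy in range(-r, r + 1):
            for dz in range(-r, r + 1):
                neigh = padded[r + dx : r + dx + nx, r + dy : r + dy + ny, r + dz : r + dz + nz]
                diff = neigh - volume
                w_s = np.exp(-(dx * dx + dy * dy + dz * dz) / (2.0 * r * r))
                w = w_s * np.exp(-(diff**2) / (2.0 * range_sigma**2))
                num += w * diff  # accumulate differences: constants pass through exactly
                den += w
    return volume + num / den


def denoise(
    stack: PhaseStack, noise: NoiseEstimate, config: PreprocessConfig | None = None
) -> PhaseStack:
    """Median (radius 2) then bilateral (radius 1) filtering, per phase.

    The bilateral range parameter is ``bilateral_range_factor × noise SD``
    (default 2), tying the photometric scale to the measured noise floor.
    A zero noise estimate makes the bilateral step an identity.  Grid and
    spacing are unchanged; constant volumes pass through exactly.
    """
    config = config or PreprocessConfig()
    footprint = _ball_footprint(config.median_radius)
    range_sigma = config.bilateral_range_factor * noise.sd_hu
    out = np.empty_like(stack.voxels)
    for p in range(stack.n_phases):
        vol = ndimage.median_filter(stack.voxels[..., p], footprint=footprint, mode="mirror")
        if range_sigma > 0:
            vol = _bilateral3d(vol, config.bilateral_distance, range_sigma)
        out[..., p] = vol
    return stack.with_voxels(out)


def measure_reference_signals(
    stack: PhaseStack,
    portal_vein_roi: RegionMask,
    unenhanced_phase: str = UNENHANCED_PHASE,
) -> ReferenceSignals:
    """Mean portal-vein signal per phase: ``I₀`` and ``I_pv`` values."""
    check_same_grid(stack, portal_vein_roi, what="portal-vein ROI")
    if portal_vein_roi.voxel_count == 0:
        raise ValueError("empty portal-vein ROI")
    mask = portal_vein_roi.voxels
    i0 = float(stack.phase(unenhanced_phase)[mask].mean())
    ipv = {
        label: float(stack.phase(label)[mask].mean())
        for label in stack.phase_labels
        if label != unenhanced_phase
    }
    return ReferenceSignals(i0=i0, ipv_per_phase=ipv)


def normalize_enhancement(
    stack: PhaseStack,
    refs: ReferenceSignals,
    unenhanced_phase: str = UNENHANCED_PHASE,
    portal_phase: str = PORTAL_PHASE,
) -> PhaseStack:
    """Portal-vein normalization: ``(I − I₀) / (I_pv − I₀) × 100`` per phase.

    Each contrast phase uses its own portal-vein signal, so portal-vein
    blood maps to 100 in every contrast phase and unenhanced blood to 0.
    The formula's denominator vanishes for the unenhanced phase itself; it
    is scaled with the portal-venous denominator instead, putting the
    whole stack on one intensity scale.
    """
    if stack.normalized:
        raise ValueError("stack is already normalized")
    out = np.empty_like(stack.voxels)
    for p, label in enumerate(stack.phase_labels):
        if label == unenhanced_phase:
            ipv = refs.ipv_per_phase[portal_phase]
        else:
            ipv = refs.ipv_per_phase[label]
        out[..., p] = (stack.voxels[..., p] - refs.i0) / (ipv - refs.i0) * 100.0
    return stack.with_voxels(out, normalized=True)


def remove_phase_baseline(stack: PhaseStack, mask: RegionMask | None = None) -> PhaseStack:
    """Subtract each phase's typical (median) signal before fractal analysis.

    The 4D analysis treats the contrast-phase axis as a fourth dimension,
    so a large enhancement step shared uniformly by all tissue would read
    as chaos even though it is plain physiology.  Subtracting the spatial
    median per phase (over ``mask`` if given, else the whole volume)
    re-expresses the stack as *deviations from the volume-typical
    time-intensity curve*: tissue that enhances like its surroundings
    becomes flat along the phase axis, while abnormal enhancement dynamics
    (e.g. a hypo-enhancing tumour core) and spatial texture are preserved.
    Spatial contrasts within each phase are unchanged (per-phase constant
    shift).
    """
    out = np.empty_like(stack.voxels)
    for p in range(stack.n_phases):
        vol = stack.voxels[..., p]
        ref = vol[mask.voxels] if mask is not None else vol
        out[..., p] = vol - np.median(ref)
    return stack.with_voxels(out)


def _best_integer_shift(
    reference: np.ndarray, moving: np.ndarray, radius: int
) -> tuple[tuple[int, int, int], float]:
    """Integer displacement ``d`` with ``moving ≈ roll(reference, d)``,
    searched within ±``radius`` voxels per axis (circular), plus the
    normalized correlation at the optimum."""
    ref = reference - reference.mean()
    mov = moving - moving.mean()
    denom = np.sqrt((ref**2).sum() * (mov**2).sum())
    if denom == 0:
        return (0, 0, 0), 0.0
    corr = np.fft.ifftn(np.fft.fftn(ref) * np.conj(np.fft.fftn(mov))).real
    offsets = np.arange(-radius, radius + 1)
    window = corr[
        np.ix_(*(offsets % n for n in corr.shape))
    ]  # corr[s] = correlation after rolling `moving` by s
    flat = int(np.argmax(window))
    idx = np.unravel_index(flat, window.shape)
    displacement = tuple(int(-offsets[i]) for i in idx)
    return displacement, float(window[idx]) / denom


def align_phases(
    stack: PhaseStack,
    reference_phase: int | str = 0,
    config: PreprocessConfig | None = None,
) -> tuple[PhaseStack, list[ShiftReport]]:
    """Correct rigid integer-voxel shifts between phases.

    Each non-reference phase's integer displacement relative to the
    reference (within ±``shift_search_radius`` voxels per axis) is found
    by maximizing normalized cross-correlation; the phase is translated
    back by the negated displacement.  The report lists the *detected
    displacement* per phase.  Degenerate (constant) phases or
    correlations below ``alignment_confidence`` are left unshifted and
    flagged low-confidence.  Corrections are applied circularly; with
    genuine rigid shifts only the wrapped boundary voxels are affected.
    """
    config = config or PreprocessConfig()
    ref_idx = reference_phase if isinstance(reference_phase, int) else stack.phase_index(reference_phase)
    reference = stack.voxels[..., ref_idx]
    radius = config.shift_search_radius

    out = stack.voxels.copy()
    reports = []
    for p, label in enumerate(stack.phase_labels):
        if p == ref_idx:
            reports.append(ShiftReport(label, (0, 0, 0), 1.0, False))
            continue
        displacement, score = _best_integer_shift(reference, stack.voxels[..., p], radius)
        low_conf = bool(score < config.alignment_confidence)
        if low_conf:
            displacement = (0, 0, 0)
        if displacement != (0, 0, 0):
            correction = tuple(-d for d in displacement)
            out[..., p] = np.roll(stack.voxels[..., p], correction, axis=(0, 1, 2))
        reports.append(ShiftReport(label, displacement, score, low_conf))
    return stack.with_voxels(out), reports
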