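"""Seeded synthetic multiphasic phantoms with known ground truth.

The phantom emulates the structure the method targets: a hypo-enhancing
ellipsoidal tumour core, a rim shell that is *intensity-matched to the
surrounding pancreas in every phase* (mean contrast zero — invisible on raw
images) but carries a rougher perfusion texture, smoother background
parenchyma, a bright portal-vein cylinder for intensity normalization, and
a homogeneous muscle box for noise estimation.  Textures are fractional
Brownian motion (fBm) fields whose Hurst exponent sets their roughness:
the graph of a d-dimensional fBm field with Hurst ``H`` has fractal
dimension ``d + 1 − H``, so lower ``H`` means more chaos.

Everything is deterministic per seed: identical spec + seed give
bit-identical volumes and masks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .types import DEFAULT_PHASE_LABELS, PhaseStack, RegionMask


def make_fbm_field(
    shape: Sequence[int],
    hurst: float,
    seed: int,
    increment_sd: float = 1.0,
    outer_scale: float | None = None,
) -> np.ndarray:
    """Zero-mean fractional-Brownian-motion field by spectral synthesis.

    Complex Gaussian spectral coefficients are shaped with the isotropic
    power spectrum ``S(f) ∝ f^−(2H + d)`` (``d = len(shape)``), which gives
    increments whose variance grows as ``r^{2H}`` with lag ``r``.  The
    discrete spectrum is alias-folded over the first-order spectral images
    (``k ∈ {−1, 0, 1}^d``): without folding the Nyquist truncation leaves
    the lattice field too smooth at lags of a few voxels, exactly the
    scales blanket analysis probes.  The field is rescaled so that the
    standard deviation of its voxel-to-voxel (lag-1) differences equals
    ``increment_sd`` — the natural amplitude unit for blanket analysis,
    whose vertical step is one gray-level.

    ``outer_scale`` (voxels), if given, switches to a von Kármán-type
    spectrum ``S(f) ∝ (f² + f₀²)^−(2H+d)/2`` with ``f₀ = 1/outer_scale``:
    fBm scaling at lags below the outer scale, stationary (finite,
    realization-stable variance) beyond it.  True fBm is non-stationary —
    its large-scale swings grow without bound — which is right for
    validating a fractal estimator but wrong for tissue, whose
    heterogeneity has a finite correlation length.

    Deterministic per ``seed``.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError(f"hurst must be in (0, 1), got {hurst}")
    shape = tuple(int(n) for n in shape)
    d = len(shape)
    if d not in (3, 4):
        raise ValueError("supported supports are 3D and 4D")

    rng = np.random.default_rng(seed)
    white = rng.standard_normal(shape)
    spectrum = np.fft.fftn(white)

    grids = np.meshgrid(*(np.fft.fftfreq(n) for n in shape), indexing="ij", sparse=True)
    f0sq = 0.0 if outer_scale is None else (1.0 / float(outer_scale)) ** 2
    power = np.zeros(shape)
    for image in itertools.product((-1.0, 0.0, 1.0), repeat=d):
        f2 = np.asarray(sum((g + k) ** 2 for g, k in zip(grids, image)), dtype=np.float64)
        f2 = f2 + f0sq
        if not any(image) and f0sq == 0.0:
            f2 = f2.copy()
            f2.flat[0] = np.inf  # kill the DC mode
        power += f2 ** (-(2.0 * hurst + d) / 2.0)
    amplitude = np.sqrt(power)
    amplitude.flat[0] = 0.0

    fieldv = np.fft.ifftn(spectrum * amplitude).real
    inc_var = np.mean(
        [np.diff(fieldv, axis=ax).var() for ax in range(d)]
    )
    fieldv *= increment_sd / np.sqrt(inc_var)
    return fieldv - fieldv.mean()


@dataclass
class TextureSpec:
    """Perfusion texture of one tissue region.

    ``hurst`` and ``amplitude`` (HU, lag-1 increment SD) describe the
    phase-coherent spatial texture.  ``dynamic_sd`` (HU, total SD) sets a
    per-phase *incoherent* component — independent smooth fields per
    contrast phase — modelling spatially patchy enhancement dynamics:
    chaotically perfused tissue enhances differently voxel to voxel, which
    is 4D chaos even where the mean contrast is zero.
    """

    hurst: float
    amplitude: float
    dynamic_sd: float
    #: spatial Hurst of the incoherent component (patch smoothness)
    dynamic_hurst: float = 0.5
    #: outer correlation scale of tissue heterogeneity, voxels
    outer_scale: float = 10.0


@dataclass
class EllipsoidSpec:
    """Tumour-core geometry, per-phase mean intensity, and texture."""

    centre_mm: tuple[float, float, float] = (33.6, 33.6, 22.4)
    semi_axes_mm: tuple[float, float, float] = (14.0, 12.0, 10.0)
    hu_per_phase: tuple[float, ...] = (40.0, 55.0, 65.0)  # hypo-enhancing
    texture: TextureSpec = field(
        default_factory=lambda: TextureSpec(hurst=0.5, amplitude=10.0, dynamic_sd=3.0)
    )


@dataclass
class RimSpec:
    """Rim shell: intensity-matched to background (mean contrast zero in
    every phase) but with rough, phase-incoherent perfusion texture."""

    thickness_mm: float = 5.6
    texture: TextureSpec = field(
        default_factory=lambda: TextureSpec(hurst=0.3, amplitude=15.0, dynamic_sd=45.0)
    )


@dataclass
class BackgroundSpec:
    """Pancreatic parenchyma surrounding the tumour: smooth, coherent."""

    hu_per_phase: tuple[float, ...] = (40.0, 110.0, 90.0)
    texture: TextureSpec = field(
        default_factory=lambda: TextureSpec(hurst=0.8, amplitude=6.0, dynamic_sd=2.0)
    )


@dataclass
class VesselSpec:
    """Portal-vein cylinder (the intensity-normalization reference)."""

    centre_xy_mm: tuple[float, float] = (53.0, 53.0)
    radius_mm: float = 5.0
    hu_per_phase: tuple[float, ...] = (45.0, 170.0, 150.0)


@dataclass
class MuscleSpec:
    """Homogeneous muscle box (the noise-estimation ROI)."""

    corner_mm: tuple[float, float, float] = (3.5, 3.5, 3.5)
    size_mm: tuple[float, float, float] = (14.0, 14.0, 14.0)
    hu: float = 55.0


@dataclass
class PhantomSpec:
    """Complete description of one synthetic multiphasic case."""

    grid_shape: tuple[int, int, int] = (96, 96, 64)
    spacing: tuple[float, float, float] = (0.7, 0.7, 0.7)
    phase_labels: tuple[str, ...] = DEFAULT_PHASE_LABELS
    core: EllipsoidSpec = field(default_factory=EllipsoidSpec)
    rim: RimSpec = field(default_factory=RimSpec)
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    portal_vein: VesselSpec = field(default_factory=VesselSpec)
    muscle: MuscleSpec = field(default_factory=MuscleSpec)
    noise_sd_hu: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rim.texture.hurst >= self.background.texture.hurst:
            raise ValueError("rim texture must be rougher (lower Hurst) than background")
        if min(self.core.semi_axes_mm) <= 0 or self.rim.thickness_mm <= 0:
            raise ValueError("core semi-axes and rim thickness must be positive")
        n = len(self.phase_labels)
        for name, levels in (
            ("core", self.core.hu_per_phase),
            ("background", self.background.hu_per_phase),
            ("portal_vein", self.portal_vein.hu_per_phase),
        ):
            if len(levels) != n:
                raise ValueError(f"{name} needs {n} per-phase intensity levels")


@dataclass
class PhantomTruth:
    """Ground-truth masks and sizes for one phantom realisation."""

    masks: dict[str, RegionMask]
    true_volume_ml: dict[str, float]
    true_feret_mm: dict[str, float]
    analytic_volume_ml: dict[str, float]
    spec: PhantomSpec


def _region_texture(
    shape3: tuple[int, int, int], n_phases: int, tex: TextureSpec, seed: int
) -> np.ndarray:
    """4D texture: phase-coherent spatial fBm + per-phase incoherent fields."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_phases + 1)
    out = np.empty(shape3 + (n_phases,), dtype=np.float64)
    coherent = (
        make_fbm_field(
            shape3,
            tex.hurst,
            int(seeds[0]),
            increment_sd=tex.amplitude,
            outer_scale=tex.outer_scale,
        )
        if tex.amplitude > 0
        else 0.0
    )
    for p in range(n_phases):
        if tex.dynamic_sd > 0:
            dyn = make_fbm_field(
                shape3, tex.dynamic_hurst, int(seeds[1 + p]), outer_scale=tex.outer_scale
            )
            dyn *= tex.dynamic_sd / dyn.std()
        else:
            dyn = 0.0
        out[..., p] = coherent + dyn
    return out


def _ellipsoid_mask(spec: PhantomSpec, grow_mm: float = 0.0) -> np.ndarray:
    coords = [
        np.arange(n) * s for n, s in zip(spec.grid_shape, spec.spacing)
    ]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij", sparse=True)
    cx, cy, cz = spec.core.centre_mm
    ax, ay, az = (a + grow_mm for a in spec.core.semi_axes_mm)
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 + ((zz - cz) / az) ** 2 <= 1.0


def _geometry_inside(mask: np.ndarray, what: str) -> None:
    for axis in range(mask.ndim):
        edge = [slice(None)] * mask.ndim
        for pos in (0, -1):
            edge[axis] = pos
            if mask[tuple(edge)].any():
                raise ValueError(f"{what} touches the grid boundary")


def make_pda_phantom(spec: PhantomSpec | None = None) -> tuple[PhaseStack, PhantomTruth]:
    """Build one seeded phantom: multiphase volume plus ground truth.

    Construction order: background base level + background texture
    everywhere; core and rim voxels get their own mean level and texture
    (the rim's mean level *is* the background level, so its contrast is
    zero in every phase); portal vein and muscle are painted homogeneous;
    global Gaussian noise is added last.

    Each region's texture is a phase-coherent 3D fBm plus independent
    per-phase smooth fields (see :class:`TextureSpec`); the rim's strongly
    incoherent dynamics make it the most chaotic region in 4D, the
    hypo-enhancing core is intermediate (its enhancement deviates
    uniformly from the parenchymal time-intensity curve), and the
    background is the least chaotic.
    """
    spec = spec if spec is not None else PhantomSpec()
    shape3 = tuple(spec.grid_shape)
    n_phases = len(spec.phase_labels)
    shape4 = shape3 + (n_phases,)
    sx, sy, sz = spec.spacing

    core = _ellipsoid_mask(spec)
    tumour = _ellipsoid_mask(spec, grow_mm=spec.rim.thickness_mm)
    rim = tumour & ~core
    _geometry_inside(tumour, "tumour")

    coords = [np.arange(n) * s for n, s in zip(shape3, spec.spacing)]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij", sparse=True)
    vx, vy = spec.portal_vein.centre_xy_mm
    vein = (xx - vx) ** 2 + (yy - vy) ** 2 <= spec.portal_vein.radius_mm**2
    vein = np.broadcast_to(vein, shape3).copy()
    if (vein & tumour).any():
        raise ValueError("portal vein intersects the tumour")

    m0 = spec.muscle.corner_mm
    m1 = tuple(c + s for c, s in zip(m0, spec.muscle.size_mm))
    muscle = (
        (xx >= m0[0]) & (xx < m1[0]) & (yy >= m0[1]) & (yy < m1[1]) & (zz >= m0[2]) & (zz < m1[2])
    )
    muscle = np.broadcast_to(muscle, shape3).copy()
    if (muscle & (tumour | vein)).any():
        raise ValueError("muscle box intersects another structure")

    # "remote pancreas": background clear of the other structures and the
    # volume border, so its FD reflects parenchymal texture, not edges
    margin = 4
    near_structure = ndimage.binary_dilation(tumour | vein | muscle, iterations=margin)
    interior = np.zeros(shape3, dtype=bool)
    interior[margin:-margin, margin:-margin, margin:-margin] = True
    pancreas = ~near_structure & interior

    root = np.random.default_rng(spec.seed)
    seeds = root.integers(0, 2**31 - 1, size=4)
    bg_tex = _region_texture(shape3, n_phases, spec.background.texture, int(seeds[0]))
    core_tex = _region_texture(shape3, n_phases, spec.core.texture, int(seeds[1]))
    rim_tex = _region_texture(shape3, n_phases, spec.rim.texture, int(seeds[2]))
    noise = np.random.default_rng(int(seeds[3])).normal(0.0, spec.noise_sd_hu, size=shape4)

    voxels = np.empty(shape4, dtype=np.float64)
    bg_levels = np.asarray(spec.background.hu_per_phase)
    voxels[:] = bg_levels + bg_tex
    for p in range(n_phases):
        vol = voxels[..., p]
        ct = core_tex[..., p][core]
        rt = rim_tex[..., p][rim]
        # textures are re-centred over their region so the region's mean
        # level is exactly the specified one (the rim's contrast is
        # exactly zero: invisible by intensity, separable only by chaos)
        vol[core] = spec.core.hu_per_phase[p] + ct - ct.mean()
        vol[rim] = bg_levels[p] + rt - rt.mean()
        vol[vein] = spec.portal_vein.hu_per_phase[p]
        vol[muscle] = spec.muscle.hu
    voxels += noise

    stack = PhaseStack(
        voxels=voxels, spacing=spec.spacing, phase_labels=spec.phase_labels, normalized=False
    )

    masks = {
        "core": RegionMask(core, spec.spacing, "core"),
        "rim": RegionMask(rim, spec.spacing, "rim"),
        "tumour": RegionMask(tumour, spec.spacing, "tumour"),
        "pancreas": RegionMask(pancreas, spec.spacing, "pancreas"),
        "portal_vein": RegionMask(vein, spec.spacing, "portal_vein"),
        "muscle": RegionMask(muscle, spec.spacing, "muscle"),
    }
    from .measure import volume_ml  # local import avoids a cycle

    true_volume = {name: volume_ml(m) for name, m in masks.items()}

    a, b, c = spec.core.semi_axes_mm
    t = spec.rim.thickness_mm
    analytic_volume = {
        "core": 4.0 / 3.0 * np.pi * a * b * c / 1000.0,
        "tumour": 4.0 / 3.0 * np.pi * (a + t) * (b + t) * (c + t) / 1000.0,
    }
    true_feret = {
        "core": 2.0 * max(spec.core.semi_axes_mm),
        "tumour": 2.0 * (max(spec.core.semi_axes_mm) + t),
    }
    truth = PhantomTruth(
        masks=masks,
        true_volume_ml=true_volume,
        true_feret_mm=true_feret,
        analytic_volume_ml=analytic_volume,
        spec=spec,
    )
    return stack, truth
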