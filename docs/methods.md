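# Methods

This note documents the models, conventions, and design choices behind
`fractalct`: what is computed, why the defaults are what they are, and
what the synthetic phantoms do and do not establish about real data.

## 1. The 4D signal and its standardisation

A case is a `PhaseStack`: a 4D array indexed `(x, y, z, phase)` whose
last axis runs over the contrast-enhancement phases (unenhanced,
pancreatic-parenchymal, portal-venous).  World coordinates are
`index × spacing` in mm — no origin or orientation handling; masks must
share the stack grid exactly.

Standardisation proceeds in five steps.

**Rigid alignment.**  Full deformable registration is assumed done
upstream; `align_phases` is a consistency fallback that detects and
corrects integer-voxel displacements (±10 voxels per axis by default) by
FFT cross-correlation.  The detected displacement is reported per phase;
corrections are applied circularly, so only wrapped border voxels are
affected.  A normalized correlation below 0.3, or a constant phase,
yields a zero shift with a low-confidence flag.

**Isotropic resampling.**  Every phase is linearly resampled to a common
isotropic spacing (default 0.7 mm, the in-plane resolution of typical
abdominal CT).  The new grid has `round(n·s/target)` voxels per axis, so
the physical extent is preserved within one voxel; masks are resampled
nearest-neighbour so no labels are invented.

**Noise-adaptive denoising.**  Image noise is the sample SD of an
erector-muscle ROI.  Each phase is filtered with a 3D median (spherical
footprint, radius 2 voxels) followed by a 3D bilateral filter (Chebyshev
radius 1, spatial Gaussian σ = 1 voxel).  The bilateral range parameter
is `2 × noise SD`: twice the noise floor separates noise (smoothed) from
tissue contrast (preserved); the factor is a config knob
(`bilateral_range_factor`).  The bilateral accumulates *differences*
from the centre voxel, so constant volumes pass through bit-exactly; a
zero noise estimate makes it an identity.

**Portal-vein intensity normalization.**  With `I₀` the mean unenhanced
portal-vein signal and `I_pv` the mean portal-vein signal of a contrast
phase, every voxel is mapped to `I = (I_voxel − I₀)/(I_pv − I₀) × 100`,
per phase, so portal-vein blood reads 100 in every contrast phase and
unenhanced blood reads 0.  This cancels circulation and injection-timing
differences between patients.  The formula's denominator vanishes for
the unenhanced phase itself; that phase is scaled with the portal-venous
denominator, putting the whole stack on one scale.  Means (not medians)
reduce the vein-ROI values; the choice is inconsequential for a
homogeneous vessel ROI.

**Phase-baseline removal.**  The fractal analysis treats the phase axis
as a fourth spatial dimension with unit steps.  Healthy parenchyma gains
roughly 70 HU between the unenhanced and parenchymal phases — a step
shared uniformly by nearly all tissue.  Fed directly to the 4D
estimator, this physiological step dominates the small scales and makes
*every* region read as chaotic (measured on phantoms: pancreas global FD
≈ 4.6 regardless of its texture).  `remove_phase_baseline` therefore
subtracts each phase's spatial median, re-expressing the stack as
deviations from the volume-typical time-intensity curve.  Tissue that
enhances like its surroundings becomes flat along the phase axis, while
abnormal dynamics — the hypo-enhancing tumour core, the rim's patchy
enhancement — are preserved, as is all spatial texture (the subtraction
is a per-phase constant).  This is the package's resolution of the
genuinely open design question of how to weight the phase axis: unit
weight, applied to enhancement *deviations*.

## 2. Blanket fractal dimension in 4D

The estimator moulds two blankets to the texture `g`:
`u₀ = b₀ = g`, and for ε = 1, 2, …

    u_ε(x) = max( u_{ε−1}(x) + 1,  max_{y ∈ N(x)} u_{ε−1}(y) )
    b_ε(x) = min( b_{ε−1}(x) − 1,  min_{y ∈ N(x)} b_{ε−1}(y) )

with `N(x)` the 8 direct (city-block) neighbours in 4D.  All boundaries,
including the 3-sample phase axis, are mirror-reflected; because the
city-block max/min filters preserve reflection symmetry, iterating on
the array equals iterating on its infinite mirror extension.

The surface measure at scale ε is the *volume growth*

    A(ε) = (V(ε) − V(ε−1)) / 2,      V(ε) = Σ (u_ε − b_ε),  V(0) = 0,

and the FD is `4 − slope` of the least-squares line of `log A` on
`log ε`, clamped into [4, 5] with the clamped fraction reported.
The derivative form was chosen over the cumulative `V(ε)/(2ε)` after
direct comparison on validation fields: the cumulative form integrates
all sub-scale contributions and flattens the regression (biases of up to
−0.40 at H = 0.3 on fBm fields), while the derivative form recovers
`5 − H` within ±0.07 for H ∈ {0.3, 0.5, 0.7}.  Both forms give
`A(ε) = N` for a flat region of N voxels at every scale, so all
closed-form limits are unchanged.

Numerical conventions: the per-voxel vertical step is one gray-level, so
FD estimates are amplitude-dependent below increments of order one
(textures should be analysed in normalized units, where tissue contrast
spans tens of units); regression responses are centred before fitting so
a constant `A` yields slope exactly 0 and FD exactly 4.0; `A > 0` always
holds because `u − b` grows by at least 2 per iteration; a zero-variance
response defines R² = 1 (degenerate perfect fit).

**Local maps** evaluate each voxel's vicinity: the blanket volume is
summed over the Chebyshev window of radius 3 centred on the voxel
(window and blankets both see the mirror extension, including across the
phase axis) at scales ε ∈ {1, 2, 3}, and the fit is done voxelwise.  The
map is reported at the central phase index.  The implementation uses
separable window sums over globally iterated blankets; it agrees with a
naive reference that materializes every window independently
(`fractalct.reference`) to float round-off (< 1e-10), which the test
suite asserts.

**Global FD** iterates blankets on the full stack and restricts the
volume sums to the ROI voxels (across all phases, normalized by the
phase count so a flat ROI of n voxels has `A(ε) = n`).  Default scales
are ε = 1 … min(8, smallest ROI bounding-box extent / 2).  Values at
ROI boundaries incorporate neighbouring tissue within city-block
distance ε; regions thinner than about twice the largest scale will
partially reflect their surroundings.

## 3. Size measurement

Distances are between voxel centres (a single voxel has diameter 0; add
one voxel if full-extent diameters are wanted).  Volume is exactly
`voxel count × voxel volume`.  The 3D Feret diameter is the maximum
pairwise voxel-centre distance, computed on convex-hull vertices (brute
force for degenerate flat clouds) — equal to exhaustive search, which
the tests verify.  The RECIST-style diameter is the maximum in-plane
(fixed-z) pairwise distance over axial slices, and can never exceed the
Feret diameter.  FD-threshold segmentation returns the 26-connected
component of `{FD ≥ threshold}` containing a seed voxel; 26-connectivity
is deliberately permissive to follow thin rims, and raising the
threshold can only shrink the mask.  No numeric FD cut-off is claimed to
replicate human reader behaviour; the threshold is an explicit parameter
(the examples calibrate it midway between the pancreas-mean and rim-mean
local FD of the case at hand).

## 4. Agreement statistics

Differences follow the *reference − test* convention, so a method that
underestimates has a positive mean difference.  Bland–Altman limits are
`mean ± 1.96·SD` (classical form, not t-quantiles).  Proportional bias
is the regression of difference on pairwise mean; the correlation line
regresses test on reference, both with normal-theory 95% CIs.  Pairwise
group comparisons use the Mann–Whitney U test (unpaired) or the Wilcoxon
signed-rank test (paired) — the paired member of the rank-test family —
with exact p-values for ≤ 10 observations per group without ties and the
tie-corrected normal approximation otherwise, Bonferroni-adjusted by the
number of pairwise comparisons; the Kruskal–Wallis omnibus is reported
unadjusted.  The F-test statistic is the larger variance over the
smaller (F ≥ 1), two-sided.  Inter-reader relative discrepancy is
`|r₁ − r₂| / mean(r₁, r₂) × 100` — the symmetric denominator — reported
as median and IQR with Spearman's ρ.

## 5. Synthetic phantoms: what they emulate

`make_pda_phantom` builds a 96×96×64 volume at 0.7 mm with three phases:

- **background pancreas** at (40, 110, 90) HU across phases — normal
  parenchyma enhances strongly in the parenchymal phase;
- an ellipsoidal **tumour core** (semi-axes 14, 12, 10 mm) at
  (40, 55, 65) HU — hypo-enhancing, the part visible on CT;
- a 5.6 mm **rim shell** whose mean intensity *equals the background in
  every phase* (enforced exactly), encoding the method's central
  premise: the rim is invisible by intensity and separable only by
  chaos;
- a **portal-vein** cylinder at (45, 170, 150) HU for normalization and
  a homogeneous **muscle** box for noise estimation;
- additive Gaussian noise (8 HU, typical of soft-kernel abdominal CT).

Tissue texture has two components per region.  A phase-coherent spatial
field sets ordinary heterogeneity (Hurst/amplitude: background 0.8 / 6
HU, core 0.5 / 10 HU, rim 0.3 / 15 HU).  A phase-*incoherent* component
— independent smooth fields per phase, total SD: background 2, core 3,
rim 45 HU — models spatially patchy enhancement dynamics: chaotically
arranged vasculature makes neighbouring voxels enhance differently, the
actual physiological signature of rim chaos.  This component is
essential: purely spatial roughness does not survive the prescribed
median + bilateral denoising (measured: structure-function slopes of
equal-increment fBm fields converge to ≈ 0.75–0.85 after filtering,
regardless of input Hurst), whereas phase-incoherent patchiness is
untouched by per-phase 3D filters.  The rim's dynamic SD (45 HU) was set
above the core's uniform enhancement deviation (≈ 44 normalized units
relative to the parenchymal time-intensity curve), so the chaos ordering
rim > core > pancreas is built into the construction, as is the CT
size-underestimation analogue.  All fields use a von Kármán-type
spectrum — fBm scaling below a 10-voxel outer correlation scale,
stationary beyond — because true fBm's unbounded large-scale swings
would imply unrealistic ±100 HU parenchyma gradients and make regional
statistics realization-unstable.

`make_fbm_field` with `outer_scale=None` generates *pure* fBm by
spectral synthesis for estimator validation, with first-order alias
folding of the power spectrum (without it, Nyquist truncation leaves the
lattice field markedly smoother than fBm at lags 1–4, exactly the
blanket scales).  Fields are normalized by their lag-1 increment SD, the
natural amplitude unit for an estimator whose vertical step is one
gray-level; validation uses increment SD 60 so that texture, not the
unit step, dominates across the fitted scales.

**What phantom results do and do not show.**  Passing tests establish
that the chain — standardisation, 4D blanket estimation, FD-threshold
segmentation, size measurement — behaves as designed on data with the
assumed statistical structure (region-wise stationary textures, known
noise, exact co-registration, a rim whose chaos exceeds its
surroundings').  They do not establish clinical performance: real tumours
have irregular geometry, partial-volume boundaries, registration error,
beam-hardening and organ anatomy that the phantom deliberately omits.

## 6. Problem sizes and determinism

The test suite and the acceptance script use the defaults above: fBm
validation on 32×32×32×8 fields (5 seeds per Hurst value), chaos-gradient
and segmentation checks on ten 96×96×64 phantoms, statistics calibration
on 1000 null replicates; the whole suite runs in a few minutes on one
CPU.  Every random quantity derives from an explicit integer seed;
identical configuration and seed reproduce byte-identical FD maps and
CSV reports, which is asserted at file level.  The flat-texture limit
(FD exactly 4) is exact for constant stacks at representable gray
levels; the phantom flat-limit check uses a uniform phantom (all regions
at one level), since region-boundary intensity steps are genuine 4D
structure and register as chaos by construction.
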