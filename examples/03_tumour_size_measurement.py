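"""Tumour size from FD maps vs. a raw-CT intensity threshold.

The phantom's tumour rim has zero mean contrast — an intensity threshold
on the raw portal-venous phase can only find the hypo-enhancing core and
underestimates the tumour, while FD-threshold segmentation recovers
core + rim.
"""

import numpy as np
from scipy import ndimage

from fractalct import (
    PhantomSpec,
    RegionMask,
    denoise,
    estimate_noise,
    local_fd_map,
    make_pda_phantom,
    measure_mask,
    measure_reference_signals,
    normalize_enhancement,
    remove_phase_baseline,
    segment_fd_threshold,
)

raw, truth = make_pda_phantom(PhantomSpec(seed=0))
true_volume = truth.true_volume_ml["tumour"]
print(f"true tumour volume (core + rim): {true_volume:.1f} mL, "
      f"Feret {truth.true_feret_mm['tumour']:.0f} mm")

stack = denoise(raw, estimate_noise(raw, truth.masks["muscle"], 0))
ct_phase = stack.phase("portal_venous")  # what a reader sees on CT
stack = normalize_enhancement(stack, measure_reference_signals(stack, truth.masks["portal_vein"]))
stack = remove_phase_baseline(stack)

# --- CT-style segmentation: hypodense component around the seed ---
seed_point = (48, 48, 32)
hypodense = ct_phase < (65.0 + 90.0) / 2  # midway core/background contrast
labels, _ = ndimage.label(hypodense, structure=np.ones((3, 3, 3), bool))
ct_mask = RegionMask(labels == labels[seed_point], stack.spacing, "ct")
ct = measure_mask(ct_mask)

# --- FD-based segmentation: threshold midway between tissue FD levels ---
fdmap = local_fd_map(stack)
thr = (fdmap.values[truth.masks["pancreas"].voxels].mean()
       + fdmap.values[truth.masks["rim"].voxels].mean()) / 2
fd_mask = segment_fd_threshold(fdmap, thr, seed_point)
fd = measure_mask(fd_mask)

print(f"\nCT intensity threshold:  volume {ct.volume_ml:5.1f} mL  Feret {ct.feret_mm:5.1f} mm")
print(f"FD threshold ({thr:.2f}):     volume {fd.volume_ml:5.1f} mL  Feret {fd.feret_mm:5.1f} mm")
print(f"\nvolume error:  CT {abs(ct.volume_ml - true_volume):.1f} mL,  "
      f"FD {abs(fd.volume_ml - true_volume):.1f} mL")
print("CT sees only the hypo-enhancing core; the FD map recovers the full tumour.")
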