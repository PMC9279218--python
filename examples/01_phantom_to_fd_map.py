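"""Perfusion-chaos mapping of a synthetic multiphasic case.

Builds a default phantom (hypo-enhancing tumour core, intensity-matched
chaotic rim, smooth pancreas background), runs the full standardisation
chain, and compares the global fractal dimension of the three regions.
"""

from fractalct import (
    PhantomSpec,
    denoise,
    estimate_noise,
    global_fd,
    make_pda_phantom,
    measure_reference_signals,
    normalize_enhancement,
    remove_phase_baseline,
)

stack, truth = make_pda_phantom(PhantomSpec(seed=0))
print(f"phantom grid {stack.spatial_shape} at {stack.spacing[0]} mm, "
      f"{stack.n_phases} contrast phases")

noise = estimate_noise(stack, truth.masks["muscle"], phase=0)
print(f"image noise (muscle ROI): {noise.sd_hu:.1f} HU")

stack = denoise(stack, noise)
refs = measure_reference_signals(stack, truth.masks["portal_vein"])
stack = normalize_enhancement(stack, refs)
stack = remove_phase_baseline(stack)

print("\nglobal fractal dimension by region (4 = orderly, 5 = chaotic):")
for region in ("rim", "core", "pancreas"):
    res = global_fd(stack, truth.masks[region], scales=range(1, 9))
    print(f"  {region:9s} FD = {res.fd:.3f}   (log-log fit R² = {res.fit_r2:.3f})")

print(
    "\nThe tumour rim is the most chaotically perfused region, the"
    "\nhypo-enhancing core intermediate, and normal pancreas the most"
    "\norderly — although the rim is intensity-matched to the pancreas in"
    "\nevery phase and therefore invisible on the raw images."
)
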