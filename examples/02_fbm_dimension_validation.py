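"""Validating the FD estimator on fields of known fractal dimension.

The graph of a fractional-Brownian-motion field over a 4D support with
Hurst exponent H has fractal dimension 5 − H.  The blanket estimator
should recover that value from synthetic fields.
"""

import numpy as np

from fractalct import PhaseStack, RegionMask, global_fd, make_fbm_field

shape = (32, 32, 32, 8)
roi = RegionMask(np.ones(shape[:3], bool), (1, 1, 1))
labels = tuple(f"t{i}" for i in range(shape[3]))

print("Hurst   theory(5-H)   estimated FD (3 seeds)   error")
for hurst in (0.3, 0.5, 0.7):
    fds = []
    for seed in range(3):
        field = make_fbm_field(shape, hurst, seed, increment_sd=60.0)
        fds.append(global_fd(PhaseStack(field, (1, 1, 1), labels), roi, range(1, 9)).fd)
    est = np.mean(fds)
    print(f"  {hurst:.1f}      {5 - hurst:.2f}          {est:.3f}              {est - (5 - hurst):+.3f}")

print(
    "\nRough fields (low H) read close to 5, smooth fields close to 4;"
    "\nerrors of a few hundredths validate the estimator's calibration."
)
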