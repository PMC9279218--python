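"""Naive reference implementations, used to cross-check the fast paths.

These deliberately re-derive results with the most literal possible code
(explicit per-window loops, no separable filters) and are far too slow for
production use.  They exist so that the optimized implementations can be
verified against an independent route on small inputs.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .fractal import SUPPORT_DIM, FDMap
from .types import PhaseStack


def _blanket_thickness_naive(window: np.ndarray, epsilon: int) -> np.ndarray:
    """Blanket thickness ``u_ε − b_ε`` on one extracted window.

    Neighbour maxima/minima are gathered by explicit axis rolls; values
    within ``epsilon`` of the window border are edge-contaminated and must
    not be read by the caller.
    """
    upper = window.astype(np.float64).copy()
    lower = upper.copy()
    for _ in range(epsilon):
        up_n = upper.copy()
        lo_n = lower.copy()
        for axis in range(window.ndim):
            for shift in (-1, 1):
                up_n = np.maximum(up_n, np.roll(upper, shift, axis=axis))
                lo_n = np.minimum(lo_n, np.roll(lower, shift, axis=axis))
        upper = np.maximum(upper + 1.0, up_n)
        lower = np.minimum(lower - 1.0, lo_n)
    return upper - lower


def local_fd_map_naive(
    stack: PhaseStack,
    window_radius: int,
    scales: Sequence[int],
) -> FDMap:
    """Per-voxel FD by materializing every local window independently.

    For each spatial voxel (at the central phase) a window of Chebyshev
    radius ``window_radius + max(scales)`` is cut out of the mirror-padded
    volume, blankets are iterated inside it, and the inter-blanket volume
    is summed over the central ``window_radius`` part only — those values
    are unaffected by the window's own border.  The surface measure is the
    per-scale volume growth ``(V(ε) − V(ε−1)) / 2``.
    """
    scales = tuple(int(s) for s in scales)
    w = int(window_radius)
    eps_max = max(scales)
    pad = w + eps_max
    tex = np.pad(stack.voxels, pad, mode="reflect")
    nx, ny, nz, npha = stack.voxels.shape
    pc = npha // 2  # central phase plane

    x_log = np.log(np.asarray(scales, dtype=np.float64))
    fd = np.empty((nx, ny, nz), dtype=np.float64)
    n_clamped = 0
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                cx, cy, cz, cp = ix + pad, iy + pad, iz + pad, pc + pad
                win = tex[
                    cx - pad : cx + pad + 1,
                    cy - pad : cy + pad + 1,
                    cz - pad : cz + pad + 1,
                    cp - pad : cp + pad + 1,
                ]
                centre = (slice(eps_max, eps_max + 2 * w + 1),) * 4
                areas = []
                for eps in scales:
                    v_here = _blanket_thickness_naive(win, eps)[centre].sum()
                    v_prev = (
                        _blanket_thickness_naive(win, eps - 1)[centre].sum()
                        if eps > 1
                        else 0.0
                    )
                    areas.append((v_here - v_prev) / 2.0)
                slope = np.polyfit(x_log, np.log(areas), 1)[0]
                val = SUPPORT_DIM - slope
                if val < SUPPORT_DIM or val > SUPPORT_DIM + 1:
                    n_clamped += 1
                fd[ix, iy, iz] = min(max(val, SUPPORT_DIM), SUPPORT_DIM + 1)
    return FDMap(
        values=fd,
        clamped_fraction=n_clamped / fd.size,
        scales_used=scales,
        spacing=stack.spacing,
    )
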