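"""Independent brute-force references used to cross-check the fast paths."""

from __future__ import annotations

import numpy as np

from ccflow.pipeline import BinarizationParams, circular_footprint


def phansalkar_bruteforce(image: np.ndarray, params: BinarizationParams) -> np.ndarray:
    """Per-pixel Phansalkar voids via direct windowed summation.

    Pads symmetrically, then for every pixel gathers the circular window
    and computes mean/SD by direct reduction — no shared code with the
    correlate-based implementation beyond the footprint definition.
    """
    r = params.radius_px
    img = np.asarray(image, dtype=float)
    padded = np.pad(img, r, mode="symmetric")
    fp = circular_footprint(r)
    h, w = img.shape
    voids = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            win = padded[i : i + 2 * r + 1, j : j + 2 * r + 1][fp]
            m = win.mean()
            s = win.std()  # population SD
            t = m * (1.0 + params.p * np.exp(-params.q * m) + params.k * (s / params.r_norm - 1.0))
            voids[i, j] = img[i, j] < t
    return voids


def region_areas_bruteforce(mask: np.ndarray, um_per_px: float, w1: float, w2: float):
    """Ring areas by all-pairs pixel distances (use on small grids only)."""
    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    d = np.sqrt(((bg[:, None, :] - fg[None, :, :]) ** 2).sum(-1)).min(axis=1) * um_per_px
    return int(((d > 0) & (d <= w1)).sum()), int(((d > w1) & (d <= w1 + w2)).sum())
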