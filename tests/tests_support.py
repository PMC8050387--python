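"""Shared independent oracles for skeleton-length tests."""
import math

import numpy as np

from neuritequant.neurites import _enforce_unit_width

SQRT2 = math.sqrt(2.0)


def brute_force_length(mask, pixel_size_um):
    """Independent oracle: enumerate all unique 8-adjacent pixel pairs."""
    pts = [tuple(p) for p in np.argwhere(mask)]
    total = 0.0
    for i, (r1, c1) in enumerate(pts):
        for r2, c2 in pts[i + 1 :]:
            dr, dc = abs(r1 - r2), abs(c1 - c2)
            if max(dr, dc) == 1:
                total += SQRT2 if dr == 1 and dc == 1 else 1.0
    return total * pixel_size_um


def random_unit_width_mask(rng, size=24, steps=30):
    """Random 8-connected walk reduced to unit width."""
    mask = np.zeros((size, size), bool)
    r = c = size // 2
    mask[r, c] = True
    for _ in range(steps):
        dr, dc = rng.integers(-1, 2), rng.integers(-1, 2)
        r = int(np.clip(r + dr, 0, size - 1))
        c = int(np.clip(c + dc, 0, size - 1))
        mask[r, c] = True
    return _enforce_unit_width(mask)
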