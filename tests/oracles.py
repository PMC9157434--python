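"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: explicit loops / exhaustive search, no shared code with
the package internals beyond numpy.
"""

from __future__ import annotations

import math

import numpy as np


def brute_connected_components(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """4-connected components by BFS over a boolean raster."""
    seen = set()
    comps = []
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or (r, c) in seen:
                continue
            comp = set()
            stack = [(r, c)]
            while stack:
                y, x = stack.pop()
                if (y, x) in seen:
                    continue
                seen.add((y, x))
                comp.add((y, x))
                for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w and mask[ny, nx]:
                        stack.append((ny, nx))
            comps.append(comp)
    return comps


def brute_inscribed_circle(mask: np.ndarray) -> tuple[tuple[int, int], float]:
    """Exhaustive largest-inscribed-circle search.

    For every foreground pixel, the largest circle centred there is
    limited by the nearest background pixel; the best centre is the
    row-major first maximum.  Matches the distance-transform definition
    by construction of the problem, not by sharing code.
    """
    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    assert len(fg) and len(bg), "mask must contain both phases"
    best_r = -1.0
    best_c = (0, 0)
    for y, x in fg:  # row-major order from argwhere
        d2 = (bg[:, 0] - y) ** 2 + (bg[:, 1] - x) ** 2
        r = math.sqrt(float(d2.min()))
        if r > best_r + 1e-12:
            best_r = r
            best_c = (int(y), int(x))
    return best_c, best_r


def brute_alpha(unit_values: list[list[int]], metric: str = "ordinal") -> float:
    """Krippendorff's alpha by explicit pair enumeration (no coincidence matrix).

    Do is the weighted mean squared difference over all ordered value
    pairs within units; De the same over all cross-unit value pairs.
    """
    # pairable-value counts per category
    counts: dict[int, float] = {}
    for vals in unit_values:
        for v in vals:
            counts[v] = counts.get(v, 0.0) + 1.0
    cats = sorted(counts)
    n = sum(counts.values())

    def d2(a: int, b: int) -> float:
        if a == b:
            return 0.0
        if metric == "nominal":
            return 1.0
        if metric == "interval":
            return float((a - b) ** 2)
        lo, hi = min(a, b), max(a, b)
        s = sum(counts[c] for c in cats if lo <= c <= hi)
        return (s - (counts[a] + counts[b]) / 2.0) ** 2

    d_obs = 0.0
    for vals in unit_values:
        m = len(vals)
        for i in range(m):
            for j in range(m):
                if i != j:
                    d_obs += d2(vals[i], vals[j]) / (m - 1)
    d_obs /= n

    d_exp = 0.0
    for a in cats:
        for b in cats:
            d_exp += counts[a] * counts[b] * d2(a, b)
    d_exp /= n * (n - 1)
    if d_exp == 0:
        return math.nan
    return 1.0 - d_obs / d_exp
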