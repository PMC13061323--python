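"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the library code paths (and scipy.ndimage):
connected components by breadth-first flood fill over explicit
neighbour lists, hotspot survival by direct Euclidean point-to-pixel
distances.
"""

from collections import deque

import numpy as np


def flood_fill_components(mask: np.ndarray, connectivity: int = 8) -> list[set]:
    """Connected components of a boolean grid as sets of (row, col)."""
    if connectivity == 8:
        steps = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    elif connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        raise ValueError(connectivity)
    mask = np.asarray(mask, dtype=bool)
    n_rows, n_cols = mask.shape
    seen = np.zeros_like(mask)
    components = []
    for r0 in range(n_rows):
        for c0 in range(n_cols):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            comp = set()
            queue = deque([(r0, c0)])
            seen[r0, c0] = True
            while queue:
                r, c = queue.popleft()
                comp.add((r, c))
                for dr, dc in steps:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < n_rows and 0 <= cc < n_cols:
                        if mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            queue.append((rr, cc))
            components.append(comp)
    return components


def remove_small_oracle(mask: np.ndarray, min_pixels: int, connectivity: int = 8) -> np.ndarray:
    """Reference implementation of the minimum-mapping-unit filter."""
    out = np.zeros_like(np.asarray(mask, dtype=bool))
    for comp in flood_fill_components(mask, connectivity):
        if len(comp) >= min_pixels:
            for r, c in comp:
                out[r, c] = True
    return out


def hotspot_survivors_oracle(
    mask: np.ndarray,
    hotspot_xy: np.ndarray,
    grid,
    buffer_m: float,
    connectivity: int = 8,
) -> np.ndarray:
    """Reference hotspot masking: a component survives iff some hotspot is
    within buffer_m of at least one of its pixel centres."""
    out = np.zeros_like(np.asarray(mask, dtype=bool))
    for comp in flood_fill_components(mask, connectivity):
        rows = np.array([rc[0] for rc in comp])
        cols = np.array([rc[1] for rc in comp])
        px, py = grid.pixel_centres(rows, cols)
        survive = False
        for hx, hy in hotspot_xy:
            if np.sqrt((px - hx) ** 2 + (py - hy) ** 2).min() <= buffer_m:
                survive = True
                break
        if survive:
            for r, c in comp:
                out[r, c] = True
    return out
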