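"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: plain Python loops,
breadth-first search, and exhaustive search over histogram cuts.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def bfs_partition(mask: np.ndarray, connectivity: int) -> set[frozenset]:
    """Connected components of a binary mask as a set of voxel-coordinate sets."""
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros_like(mask, dtype=bool)
    parts = set()
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                comp = []
                queue = deque([(r, c)])
                seen[r, c] = True
                while queue:
                    rr, cc = queue.popleft()
                    comp.append((rr, cc))
                    for dr, dc in steps:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            queue.append((nr, nc))
                parts.add(frozenset(comp))
    return parts


def labels_to_partition(labels: np.ndarray) -> set[frozenset]:
    labels = np.asarray(labels)
    parts = set()
    for k in range(1, int(labels.max()) + 1):
        cells = frozenset(map(tuple, np.argwhere(labels == k)))
        if cells:
            parts.add(cells)
    return parts


def loop_local_threshold(image: np.ndarray, window_w: int, window_h: int, offset: float) -> np.ndarray:
    """Per-voxel windowed-mean thresholding with explicit loops."""
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    hh, hw = window_h // 2, window_w // 2
    out = np.zeros((h, w), dtype=np.uint8)
    for r in range(h):
        for c in range(w):
            r0, r1 = max(r - hh, 0), min(r + hh + 1, h)
            c0, c1 = max(c - hw, 0), min(c + hw + 1, w)
            total = 0.0
            count = 0
            for rr in range(r0, r1):
                for cc in range(c0, c1):
                    total += img[rr, cc]
                    count += 1
            if img[r, c] > total / count + offset:
                out[r, c] = 1
    return out


def brute_otsu(image: np.ndarray, n_bins: int = 256) -> float:
    """Exhaustive search over interior bin edges for max between-class variance.

    Classes are defined on the raw voxel values (v < edge vs v >= edge);
    ties go to the lowest edge.
    """
    values = np.asarray(image, dtype=float).ravel()
    edges = np.linspace(values.min(), values.max(), n_bins + 1)
    best_edge, best_var = None, -1.0
    for edge in edges[1:-1]:
        lo = values[values < edge]
        hi = values[values >= edge]
        if lo.size == 0 or hi.size == 0:
            var = 0.0
        else:
            var = lo.size * hi.size * (lo.mean() - hi.mean()) ** 2
        if var > best_var + 1e-9 * max(best_var, 1.0):
            best_var, best_edge = var, edge
    return float(best_edge)


def brute_jaccard_difference(a: np.ndarray, b: np.ndarray) -> float:
    sa = {tuple(v) for v in np.argwhere(np.asarray(a).astype(bool))}
    sb = {tuple(v) for v in np.argwhere(np.asarray(b).astype(bool))}
    return 100.0 * (1.0 - len(sa & sb) / len(sa | sb))
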