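"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive — per-pixel loops, exhaustive
enumeration — and shares no code with the package internals it checks.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np


def flood_fill_label(mask: np.ndarray, connectivity: int = 8) -> tuple[np.ndarray, int]:
    """Label components by explicit stack-based flood fill."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=int)
    if connectivity == 8:
        offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    current = 0
    for r in range(h):
        for c in range(w):
            if mask[r, c] and labels[r, c] == 0:
                current += 1
                stack = [(r, c)]
                labels[r, c] = current
                while stack:
                    rr, cc = stack.pop()
                    for dr, dc in offsets:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and labels[nr, nc] == 0:
                            labels[nr, nc] = current
                            stack.append((nr, nc))
    return labels, current


def point_in_polygon_mask(polygon: np.ndarray, width: int, height: int) -> np.ndarray:
    """Pixel-center-inside rasterization via shapely, one pixel at a time."""
    from shapely.geometry import Point, Polygon

    poly = Polygon(polygon)
    mask = np.zeros((height, width), dtype=bool)
    for r in range(height):
        for c in range(width):
            mask[r, c] = poly.contains(Point(c + 0.5, r + 0.5))
    return mask


def sliding_erosion(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Erosion as an explicit min over the footprint, zero-padded."""
    return _sliding(mask, footprint, erode=True)


def sliding_dilation(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Dilation as an explicit max over the footprint, zero-padded."""
    return _sliding(mask, footprint, erode=False)


def _sliding(mask: np.ndarray, footprint: np.ndarray, erode: bool) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    fh, fw = footprint.shape
    rh, rw = fh // 2, fw // 2
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            vals = []
            for i in range(fh):
                for j in range(fw):
                    if not footprint[i, j]:
                        continue
                    rr, cc = r + i - rh, c + j - rw
                    vals.append(mask[rr, cc] if 0 <= rr < h and 0 <= cc < w else False)
            out[r, c] = all(vals) if erode else any(vals)
    return out


def sliding_closing(mask: np.ndarray, footprint: np.ndarray, pad: int) -> np.ndarray:
    padded = np.pad(np.asarray(mask, dtype=bool), pad)
    out = sliding_erosion(sliding_dilation(padded, footprint), footprint)
    return out[pad:-pad, pad:-pad]


def sliding_opening(mask: np.ndarray, footprint: np.ndarray, pad: int) -> np.ndarray:
    padded = np.pad(np.asarray(mask, dtype=bool), pad)
    out = sliding_dilation(sliding_erosion(padded, footprint), footprint)
    return out[pad:-pad, pad:-pad]


def shifted_window_filter(mask: np.ndarray, footprint: np.ndarray, erode: bool) -> np.ndarray:
    """Sliding-window min/max filter via explicit per-offset shifts.

    Vectorized over pixels but still a direct transcription of the
    definition: each output pixel is the min (erosion) or max (dilation)
    of the input over the footprint offsets, with outside-the-array
    treated as background.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    fh, fw = footprint.shape
    rh, rw = fh // 2, fw // 2
    out = np.ones_like(mask) if erode else np.zeros_like(mask)
    for i in range(fh):
        for j in range(fw):
            if not footprint[i, j]:
                continue
            dr, dc = i - rh, j - rw
            shifted = np.zeros_like(mask)
            rs0, rs1 = max(0, -dr), min(h, h - dr)
            cs0, cs1 = max(0, -dc), min(w, w - dc)
            shifted[rs0:rs1, cs0:cs1] = mask[rs0 + dr:rs1 + dr, cs0 + dc:cs1 + dc]
            out = (out & shifted) if erode else (out | shifted)
    return out


def shifted_window_closing(mask: np.ndarray, footprint: np.ndarray, pad: int) -> np.ndarray:
    padded = np.pad(np.asarray(mask, dtype=bool), pad)
    out = shifted_window_filter(
        shifted_window_filter(padded, footprint, erode=False), footprint, erode=True)
    return out[pad:-pad, pad:-pad]


def shifted_window_opening(mask: np.ndarray, footprint: np.ndarray, pad: int) -> np.ndarray:
    padded = np.pad(np.asarray(mask, dtype=bool), pad)
    out = shifted_window_filter(
        shifted_window_filter(padded, footprint, erode=True), footprint, erode=False)
    return out[pad:-pad, pad:-pad]


def border_flood_fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill holes by flood-filling background from the border (4-connected)."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    reachable = np.zeros((h, w), dtype=bool)
    stack = [(r, c) for r in range(h) for c in (0, w - 1) if not mask[r, c]]
    stack += [(r, c) for c in range(w) for r in (0, h - 1) if not mask[r, c]]
    for r, c in stack:
        reachable[r, c] = True
    while stack:
        r, c = stack.pop()
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w and not mask[nr, nc] and not reachable[nr, nc]:
                reachable[nr, nc] = True
                stack.append((nr, nc))
    return mask | ~reachable


def max_matching_dt(overlap: np.ndarray) -> int:
    """Maximum one-to-one matching size by exhaustive enumeration.

    ``overlap[i, j]`` is truthy when predicted component i may match
    ground-truth component j.  Feasible only for small instances.
    """
    n_pred, n_gt = overlap.shape
    if n_pred == 0 or n_gt == 0:
        return 0
    small, large, table = (
        (n_pred, n_gt, overlap) if n_pred <= n_gt else (n_gt, n_pred, overlap.T)
    )
    best = 0
    for perm in permutations(range(large), small):
        best = max(best, sum(1 for i, j in enumerate(perm) if table[i, j]))
    return best
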