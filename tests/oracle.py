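"""Brute-force reference implementations used only as test oracles.

Deliberately naive (explicit loops, no shared code with the package) so
each stays independent of the production path it checks.
"""

from __future__ import annotations

import math

import numpy as np


def histogram_tally(pixels: np.ndarray) -> np.ndarray:
    counts = np.zeros(256, dtype=int)
    for value in np.asarray(pixels).ravel():
        counts[int(value)] += 1
    return counts


def cross_corr_quadloop(image: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Eq.-style raw correlation: quadruple loop over valid placements."""
    image = np.asarray(image)
    template = np.asarray(template)
    h, w = image.shape
    u, v = template.shape
    out = np.zeros((h - u + 1, w - v + 1), dtype=np.int64)
    for i in range(h - u + 1):
        for j in range(w - v + 1):
            acc = 0
            for x in range(u):
                for y in range(v):
                    acc += int(template[x, y]) * int(image[i + x, j + y])
            out[i, j] = acc
    return out


def ncc_windowed(image: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Direct per-window normalized cross-correlation."""
    image = np.asarray(image, dtype=float)
    template = np.asarray(template, dtype=float)
    h, w = image.shape
    u, v = template.shape
    tz = template - template.mean()
    den_t = math.sqrt(float((tz * tz).sum()))
    out = np.zeros((h - u + 1, w - v + 1))
    for i in range(h - u + 1):
        for j in range(w - v + 1):
            patch = image[i : i + u, j : j + v]
            pz = patch - patch.mean()
            den_p = math.sqrt(float((pz * pz).sum()))
            if den_p < 1e-12 or den_t < 1e-12:
                out[i, j] = 0.0
            else:
                out[i, j] = float((tz * pz).sum()) / (den_t * den_p)
    return out


def _disk_offsets(radius: int) -> list[tuple[int, int]]:
    return [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= radius * radius
    ]


def opening_bruteforce(mask: np.ndarray, radius: int) -> np.ndarray:
    """Morphological opening with a disc: plain erosion then dilation."""
    mask = np.asarray(mask).astype(bool)
    offsets = _disk_offsets(radius)
    h, w = mask.shape

    def erode(m):
        out = np.zeros_like(m)
        for r in range(h):
            for c in range(w):
                out[r, c] = all(
                    0 <= r + dr < h and 0 <= c + dc < w and m[r + dr, c + dc]
                    for dr, dc in offsets
                )
        return out

    def dilate(m):
        out = np.zeros_like(m)
        for r in range(h):
            for c in range(w):
                out[r, c] = any(
                    0 <= r + dr < h and 0 <= c + dc < w and m[r + dr, c + dc]
                    for dr, dc in offsets
                )
        return out

    return dilate(erode(mask))


def flood_fill_areas(mask: np.ndarray) -> list[int]:
    """Areas of 8-connected components via BFS flood fill."""
    mask = np.asarray(mask).astype(bool)
    seen = np.zeros_like(mask)
    h, w = mask.shape
    areas = []
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and not seen[r0, c0]:
                stack = [(r0, c0)]
                seen[r0, c0] = True
                area = 0
                while stack:
                    r, c = stack.pop()
                    area += 1
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                areas.append(area)
    return areas
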