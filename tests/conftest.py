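"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the code paths they check: flood
fill by explicit BFS, neighbor counting by python loops, Otsu by
exhaustive threshold search, disk dilation by per-pixel distance tests.
"""

from __future__ import annotations

import math

import numpy as np
import pytest


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def flood_fill_label(mask: np.ndarray) -> np.ndarray:
    """8-connected component labeling by breadth-first search."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    h, w = mask.shape
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and labels[r0, c0] == 0:
                current += 1
                stack = [(r0, c0)]
                labels[r0, c0] = current
                while stack:
                    r, c = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (
                                0 <= rr < h and 0 <= cc < w
                                and mask[rr, cc] and labels[rr, cc] == 0
                            ):
                                labels[rr, cc] = current
                                stack.append((rr, cc))
    return labels


def neighbor_counts(skel: np.ndarray) -> np.ndarray:
    """Per-pixel count of 8-connected skeleton neighbors, python loops."""
    skel = np.asarray(skel, dtype=bool)
    h, w = skel.shape
    out = np.zeros((h, w), dtype=int)
    for r in range(h):
        for c in range(w):
            if not skel[r, c]:
                continue
            n = 0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and skel[rr, cc]:
                        n += 1
            out[r, c] = n
    return out


def exhaustive_otsu(img: np.ndarray) -> int:
    """Otsu threshold by exhaustive search over all 256 8-bit candidates.

    Maximizes the between-class variance w0*w1*(mu0-mu1)^2 of the split
    {<= t} / {> t}; ties resolve to the smallest t.
    """
    img = np.asarray(img)
    hist = np.bincount(img.ravel().astype(int), minlength=256).astype(float)
    total = hist.sum()
    best_t, best_v = 0, -1.0
    for t in range(256):
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (np.arange(t + 1) * hist[: t + 1]).sum() / w0
        mu1 = (np.arange(t + 1, 256) * hist[t + 1 :]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


def brute_force_disk_dilation(
    pixels: list[tuple[int, int]], shape: tuple[int, int], radius: int
) -> np.ndarray:
    """Mark every pixel within euclidean distance ``radius`` of the set."""
    out = np.zeros(shape, dtype=bool)
    for r in range(shape[0]):
        for c in range(shape[1]):
            for pr, pc in pixels:
                if (r - pr) ** 2 + (c - pc) ** 2 <= radius**2:
                    out[r, c] = True
                    break
    return out


def path_steps_length(path: list[tuple[int, int]]) -> float:
    """Step-metric length: 1 per orthogonal, sqrt(2) per diagonal step."""
    total = 0.0
    for a, b in zip(path, path[1:]):
        total += math.sqrt(2.0) if (a[0] != b[0] and a[1] != b[1]) else 1.0
    return total


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng():
    return np.random.default_rng(20240612)


def random_masks(n: int, shape=(32, 32), density: float = 0.4, seed: int = 0):
    """Seeded random binary masks (smoothed a little to form blobs)."""
    rng = np.random.default_rng(seed)
    from scipy.ndimage import gaussian_filter

    masks = []
    for _ in range(n):
        field = gaussian_filter(rng.random(shape), 1.0)
        masks.append(field > np.quantile(field, 1 - density))
    return masks
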