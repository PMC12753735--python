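"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check: the flooding
oracle is a plain-Python Dijkstra priority flood, the AUC oracle counts
positive-negative score pairs, and the distance oracle minimizes over
all background pixels explicitly.
"""

from __future__ import annotations

import heapq

import numpy as np


def brute_force_distance(mask: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance to the nearest background pixel, by direct
    minimization over all background pixels (O(n^2); tiny masks only)."""
    mask = np.asarray(mask, dtype=bool)
    bg = np.argwhere(~mask)
    out = np.zeros(mask.shape, dtype=float)
    for (r, c) in np.argwhere(mask):
        out[r, c] = np.sqrt(((bg - (r, c)) ** 2).sum(axis=1).min()) if len(bg) else np.inf
    return out


def flood_oracle(image: np.ndarray, markers: np.ndarray, mask: np.ndarray,
                 compactness: float = 0.0) -> np.ndarray:
    """Priority-flood watershed: min-heap ordered by (value, entry age);
    the compact variant adds ``compactness * euclidean(pixel, seed pixel)``
    to the pushed value and assigns labels when popped.  4-connectivity,
    neighbors visited up/left/right/down."""
    h, w = image.shape
    out = (np.asarray(markers) * np.asarray(mask, bool)).astype(np.int64)
    imgr = np.asarray(image, float).ravel()
    maskr = np.asarray(mask, bool).ravel()
    outr = out.ravel()
    heap = []
    for k, idx in enumerate(np.flatnonzero(outr)):
        heapq.heappush(heap, (imgr[idx], 0, k, int(idx), int(idx)))
    age = 0
    for_offsets = [-w, -1, 1, w]
    while heap:
        value, _, _, index, source = heapq.heappop(heap)
        if compactness > 0:
            if outr[index] > 0 and index != source:
                continue
            outr[index] = outr[source]
        r, c = divmod(index, w)
        for off in for_offsets:
            nb = index + off
            nr, nc = divmod(nb, w)
            if abs(nr - r) + abs(nc - c) != 1 or not (0 <= nr < h and 0 <= nc < w):
                continue
            if not maskr[nb] or outr[nb] > 0:
                continue
            age += 1
            v = imgr[nb]
            if compactness > 0:
                sr, sc = divmod(source, w)
                v += compactness * np.hypot(nr - sr, nc - sc)
            else:
                outr[nb] = outr[index]
            heapq.heappush(heap, (v, age, age, nb, source))
    return out


def auc_pair_counting(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC: fraction of (positive, negative) pairs ranked
    correctly, ties counting one half."""
    y_true = np.asarray(y_true).astype(bool)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y_true]
    neg = scores[~y_true]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need both positive and negative samples")
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def lens_area(r1: float, r2: float, d: float) -> float:
    """Intersection area of two discs with radii r1, r2 at centre distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return np.pi * min(r1, r2) ** 2
    a1 = r1**2 * np.arccos((d**2 + r1**2 - r2**2) / (2 * d * r1))
    a2 = r2**2 * np.arccos((d**2 + r2**2 - r1**2) / (2 * d * r2))
    a3 = 0.5 * np.sqrt((-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2))
    return a1 + a2 - a3


def overlapping_disc_pair(seed: int, size: int = 96) -> np.ndarray:
    """Union mask of two discs (radii 10-16 px) whose intersection is a
    seeded 20-40% of the smaller disc's area (distance solved by bisection)."""
    r = np.random.default_rng(seed)
    r1, r2 = r.uniform(10, 16, 2)
    frac = r.uniform(0.2, 0.4)
    target = frac * np.pi * min(r1, r2) ** 2
    lo, hi = abs(r1 - r2), r1 + r2
    for _ in range(60):
        d = (lo + hi) / 2
        if lens_area(r1, r2, d) > target:
            lo = d
        else:
            hi = d
    yy, xx = np.mgrid[:size, :size]
    c = size // 2 - 4
    ang = r.uniform(0, 2 * np.pi)
    m1 = (yy - c) ** 2 + (xx - c) ** 2 <= r1**2
    m2 = (yy - c - d * np.sin(ang)) ** 2 + (xx - c - d * np.cos(ang)) ** 2 <= r2**2
    return m1 | m2
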