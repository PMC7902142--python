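"""Independent brute-force oracles the unit tests check the package against.

Everything here is deliberately naive (exhaustive enumeration, direct
pixel counting, direct formula arithmetic) and shares no code with the
implementation paths it verifies.
"""

from __future__ import annotations

import itertools

import numpy as np


def greedy_nearest_selection(centroids, keypoints):
    """Frame indices chosen per key point: nearest remaining centroid,
    earlier index on ties. Mirrors the stated selection contract by
    direct enumeration of distances."""
    remaining = list(range(len(centroids)))
    chosen = []
    for x in keypoints:
        dists = [(abs(centroids[i] - x), i) for i in remaining]
        _, best = min(dists)
        chosen.append(best)
        remaining.remove(best)
    return chosen


def closing_by_definition(binary: np.ndarray, k: int) -> np.ndarray:
    """Dilation then erosion with a k x k square on an infinite zero
    background, evaluated directly by OR/AND over shifted windows (no
    morphology library). The image is embedded with a generous zero
    margin so window edges never truncate the dilation."""
    pad = k // 2
    img = np.pad(binary > 0, k, constant_values=False)

    def shifted(a, dy, dx):
        p = np.pad(a, pad, constant_values=False)
        return p[pad + dy : pad + dy + a.shape[0], pad + dx : pad + dx + a.shape[1]]

    dil = np.zeros_like(img)
    for dy in range(-pad, pad + 1):
        for dx in range(-pad, pad + 1):
            dil |= shifted(img, dy, dx)
    ero = np.ones_like(img)
    for dy in range(-pad, pad + 1):
        for dx in range(-pad, pad + 1):
            ero &= shifted(dil, dy, dx)
    return ero[k:-k, k:-k].astype(np.uint8) * 255


def otsu_by_enumeration(values: np.ndarray) -> float:
    """Threshold maximizing between-class variance, by trying every
    candidate midpoint between distinct sorted values."""
    vals = np.sort(np.asarray(values, dtype=float))
    distinct = np.unique(vals)
    best_t, best_var = None, -np.inf
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        t = (lo + hi) / 2.0
        below, above = vals[vals < t], vals[vals >= t]
        w0, w1 = below.size / vals.size, above.size / vals.size
        var = w0 * w1 * (below.mean() - above.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def overlap_by_counting(frame: np.ndarray, mask: np.ndarray) -> float:
    """Direct double-loop pixel count of |B ∩ E| / |E|."""
    num = den = 0
    h, w = mask.shape
    for y in range(h):
        for x in range(w):
            if mask[y, x] == 255:
                den += 1
                if frame[y, x] == 255:
                    num += 1
    return num / den


def wcss(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for c in np.unique(labels):
        pts = X[labels == c]
        total += float(np.sum((pts - pts.mean(axis=0)) ** 2))
    return total


def best_constrained_bipartition(X: np.ndarray, must=(), cannot=()):
    """Exhaustive search over all nonempty 2-way partitions satisfying the
    pairwise constraints; returns (labels, wcss) or None if infeasible."""
    n = X.shape[0]
    best = None
    for bits in itertools.product([0, 1], repeat=n - 1):
        labels = np.array((0,) + bits)  # fix point 0 in cluster 0: symmetry
        if len(np.unique(labels)) < 2:
            continue
        if any(labels[a] != labels[b] for a, b in must):
            continue
        if any(labels[a] == labels[b] for a, b in cannot):
            continue
        obj = wcss(X, labels)
        if best is None or obj < best[1]:
            best = (labels, obj)
    return best
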