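"""Independent brute-force oracles used to check the package's computations.

Everything here is written from scratch with elementary algorithms
(gift wrapping, shoelace, exhaustive enumeration, normal equations) and
never calls into the implementation paths it verifies.
"""

from __future__ import annotations

import itertools

import numpy as np


def gift_wrap_hull(points: np.ndarray) -> list[int]:
    """Indices of the 2-D convex hull vertices via Jarvis march (CCW)."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 3:
        return list(range(n))
    start = min(range(n), key=lambda i: (pts[i, 1], pts[i, 0]))
    hull = [start]
    while True:
        cur = hull[-1]
        cand = (cur + 1) % n
        for j in range(n):
            if j == cur:
                continue
            a = pts[cand] - pts[cur]
            b = pts[j] - pts[cur]
            cross = a[0] * b[1] - a[1] * b[0]
            if cand == cur or cross < 0 or (
                cross == 0
                and np.dot(pts[j] - pts[cur], pts[j] - pts[cur])
                > np.dot(pts[cand] - pts[cur], pts[cand] - pts[cur])
            ):
                cand = j
        if cand == start:
            break
        hull.append(cand)
        if len(hull) > n:
            raise RuntimeError("gift wrapping failed to terminate")
    return hull


def shoelace_area(points: np.ndarray) -> float:
    """Polygon area from ordered vertices."""
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def onion_peel_area_2d(points: np.ndarray) -> float:
    """Summed areas of successive hull layers (2-D), by exhaustive peeling."""
    pts = np.asarray(points, dtype=float)
    total = 0.0
    while len(pts) >= 3:
        hull = gift_wrap_hull(pts)
        area = shoelace_area(pts[hull])
        if area == 0.0:
            break
        total += area
        keep = np.ones(len(pts), dtype=bool)
        keep[hull] = False
        pts = pts[keep]
    return total


def normal_equations_ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Coefficients from (X'X)^{-1} X'y, solved explicitly."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.linalg.solve(X.T @ X, X.T @ y)


def exhaustive_subsample_stats(values: np.ndarray, k: int, stat) -> np.ndarray:
    """stat() over every size-k subset of rows, in combination order."""
    values = np.asarray(values)
    return np.array(
        [stat(values[list(idx)]) for idx in itertools.combinations(range(len(values)), k)]
    )


def histogram_overlap_ted(obs_dist: np.ndarray, ref_dist: np.ndarray) -> float:
    """Direct tabulation of the evenness index from two distance multisets.

    Normalises each multiset by its mean, counts frequencies in
    ceil(sqrt(m)) equal bins over the pooled range by explicit loops, and
    returns 1 - L1/2. Independent of numpy.histogram.
    """
    obs = np.asarray(obs_dist, float)
    ref = np.asarray(ref_dist, float)
    obs = obs / obs.mean()
    ref = ref / ref.mean()
    m = obs.size
    bins = int(np.ceil(np.sqrt(m)))
    lo = min(obs.min(), ref.min())
    hi = max(obs.max(), ref.max())
    if lo == hi:
        return 1.0
    width = (hi - lo) / bins
    p = [0] * bins
    q = [0] * bins
    for v in obs:
        i = min(int((v - lo) / width), bins - 1)
        p[i] += 1
    for v in ref:
        i = min(int((v - lo) / width), bins - 1)
        q[i] += 1
    l1 = sum(abs(a - b) for a, b in zip(p, q)) / m
    return 1.0 - l1 / 2.0
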