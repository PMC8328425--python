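"""Individual-based trait-diversity indices: TOP, TED, and FDis.

All three operate on a cloud of points in trait space (here, z-scored
reproductive traits, d = 3) where every individual counts once — there is
no abundance weighting.

* **TOP** (trait onion peeling, trait richness) sums the d-dimensional
  measures of successive convex-hull layers: compute the hull of the cloud,
  add its area (d=2) or volume (d=3), remove the hull's vertices, and
  repeat until fewer than d+1 points remain or the remainder is affinely
  degenerate. Interior structure therefore contributes, unlike a single
  convex hull.
* **TED** (trait even distribution, trait evenness) compares the cloud's
  pairwise-distance distribution with that of a maximally even reference
  arrangement of the same size, via histogram overlap; 1 means the cloud is
  distributed as evenly as the reference.
* **FDis** (functional dispersion, trait divergence) is the mean Euclidean
  distance of the points from their unweighted centroid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from scipy.stats import qmc

__all__ = [
    "PointCloud",
    "DiversityTriple",
    "ReferenceEvenDistribution",
    "top",
    "ted",
    "fdis",
    "make_reference",
    "diversity_triple",
]


@dataclass(frozen=True)
class PointCloud:
    """n points in d-dimensional trait space."""

    points: np.ndarray

    def __post_init__(self):
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.ndim != 2 or pts.shape[0] < 1:
            raise ValueError("PointCloud requires an (n, d) array with n >= 1")
        object.__setattr__(self, "points", pts)

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def d(self) -> int:
        return self.points.shape[1]


@dataclass(frozen=True)
class DiversityTriple:
    top: float
    ted: float
    fdis: float


def _as_points(cloud) -> np.ndarray:
    if isinstance(cloud, PointCloud):
        return cloud.points
    return PointCloud(np.asarray(cloud)).points


def top(cloud) -> float:
    """Trait onion peeling: summed measure of successive convex-hull layers.

    Returns 0.0 when no full-dimensional hull exists (n <= d, or an
    affinely degenerate configuration), since a measure-zero set occupies
    no trait space.
    """
    pts = _as_points(cloud)
    d = pts.shape[1]
    if d < 2:
        raise ValueError("TOP requires dimension >= 2")
    remaining = pts
    total = 0.0
    while remaining.shape[0] >= d + 1:
        try:
            hull = ConvexHull(remaining)
        except QhullError:
            break  # affinely degenerate layer: zero measure, stop peeling
        total += hull.volume  # 'volume' is area in 2-D, volume in 3-D
        keep = np.ones(remaining.shape[0], dtype=bool)
        keep[hull.vertices] = False
        remaining = remaining[keep]
    return total


def fdis(cloud) -> float:
    """Functional dispersion: mean distance to the unweighted centroid."""
    pts = _as_points(cloud)
    centroid = pts.mean(axis=0)
    return float(np.linalg.norm(pts - centroid, axis=1).mean())


@dataclass(frozen=True)
class ReferenceEvenDistribution:
    """A maximally even arrangement of n points in the unit d-cube.

    Built once per (n, d, seed) by quasi-random initialisation followed by
    deterministic short-range-repulsion relaxation (see
    :func:`make_reference`); repeated calls are bit-identical.
    """

    points: np.ndarray
    seed: int

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def d(self) -> int:
        return self.points.shape[1]


_REFERENCE_CACHE: dict[tuple[int, int, int], ReferenceEvenDistribution] = {}


def _relax_maximin(x0: np.ndarray, n: int, d: int) -> np.ndarray:
    """Relax a start configuration toward the best-packing arrangement.

    Maximises an auxiliary separation variable t subject to every pairwise
    squared distance exceeding t^2 and the points staying in the unit cube
    (SLSQP). The optimum of this program is the maximin-distance packing,
    the natural formalisation of a "perfectly even" point arrangement.
    """
    iu = np.triu_indices(n, k=1)
    m = iu[0].size

    def neg_t(z):
        return -z[-1]

    def neg_t_grad(z):
        g = np.zeros_like(z)
        g[-1] = -1.0
        return g

    def cons_f(z):
        pts = z[:-1].reshape(n, d)
        diff = pts[iu[0]] - pts[iu[1]]
        return (diff**2).sum(axis=1) - z[-1] ** 2

    def cons_j(z):
        pts = z[:-1].reshape(n, d)
        J = np.zeros((m, n * d + 1))
        diff = pts[iu[0]] - pts[iu[1]]
        for k in range(m):
            i, j = iu[0][k], iu[1][k]
            J[k, i * d : (i + 1) * d] = 2 * diff[k]
            J[k, j * d : (j + 1) * d] = -2 * diff[k]
        J[:, -1] = -2 * z[-1]
        return J

    z0 = np.concatenate([x0.ravel(), [pdist(x0).min()]])
    bounds = [(0.0, 1.0)] * (n * d) + [(0.0, math.sqrt(d) + 1.0)]
    res = minimize(
        neg_t,
        z0,
        jac=neg_t_grad,
        method="SLSQP",
        bounds=bounds,
        constraints=[{"type": "ineq", "fun": cons_f, "jac": cons_j}],
        options={"maxiter": 300, "ftol": 1e-12},
    )
    return res.x[:-1].reshape(n, d)


def make_reference(n: int, d: int, seed: int = 0) -> ReferenceEvenDistribution:
    """Construct the even reference arrangement used by TED.

    A scrambled Halton set plus seeded random configurations are each
    relaxed by :func:`_relax_maximin`; the candidate with the largest
    minimum pairwise distance wins. For small n this recovers known
    packing optima (e.g. the four corners for n=4, d=2; the tilted
    equilateral triangle of side sqrt(6)-sqrt(2) for n=3, d=2). Results
    are cached per (n, d, seed) and bit-reproducible.
    """
    if n < 3:
        raise ValueError("reference distribution needs n >= 3")
    key = (int(n), int(d), int(seed))
    cached = _REFERENCE_CACHE.get(key)
    if cached is not None:
        return cached
    rng = np.random.default_rng(seed)
    halton = qmc.Halton(d=d, scramble=True, seed=seed)
    # restarts guard against local optima of the non-convex packing
    # program; fewer for large n where each relaxation is costlier
    n_restarts = 12 if n <= 16 else 4
    starts = [halton.random(n)] + [rng.random((n, d)) for _ in range(n_restarts - 1)]
    best_pts = None
    best_sep = -np.inf
    for x0 in starts:
        pts = _relax_maximin(x0, n, d)
        sep = pdist(pts).min()
        if sep > best_sep:
            best_sep = sep
            best_pts = pts
    # canonical row order so equality is well-defined regardless of optimizer path
    order = np.lexsort(best_pts.T[::-1])
    ref = ReferenceEvenDistribution(points=best_pts[order], seed=seed)
    _REFERENCE_CACHE[key] = ref
    return ref


def _normalized_distances(pts: np.ndarray) -> np.ndarray:
    dist = pdist(pts)
    mean = dist.mean()
    if mean == 0:
        raise ValueError("TED undefined: all points coincide")
    return dist / mean


def ted(cloud, reference: ReferenceEvenDistribution | np.ndarray) -> float:
    """Trait even distribution in (0, 1].

    Both distance multisets are normalised by their own means (making the
    index scale-free) and binned into a shared histogram with
    ceil(sqrt(n(n-1)/2)) bins over the pooled range; TED is one minus half
    the L1 distance between the two relative-frequency histograms.
    """
    pts = _as_points(cloud)
    ref_pts = reference.points if isinstance(reference, ReferenceEvenDistribution) else np.asarray(reference, float)
    if pts.shape[0] < 3:
        raise ValueError("TED needs at least 3 points")
    if ref_pts.shape != pts.shape:
        raise ValueError(
            f"reference shape {ref_pts.shape} does not match cloud shape {pts.shape}"
        )
    obs = _normalized_distances(pts)
    ref = _normalized_distances(ref_pts)
    m = obs.size
    bins = math.ceil(math.sqrt(m))
    lo = min(obs.min(), ref.min())
    hi = max(obs.max(), ref.max())
    if hi - lo <= 1e-12 * max(1.0, hi):
        # every normalized distance equals 1 (up to rounding) in both sets
        return 1.0
    p, edges = np.histogram(obs, bins=bins, range=(lo, hi))
    q, _ = np.histogram(ref, bins=bins, range=(lo, hi))
    p = p / m
    q = q / m
    return float(1.0 - 0.5 * np.abs(p - q).sum())


def diversity_triple(
    cloud, reference: ReferenceEvenDistribution | None = None, seed: int = 0
) -> DiversityTriple:
    """TOP, TED and FDis of one cloud (reference built on demand)."""
    pts = _as_points(cloud)
    if reference is None:
        reference = make_reference(pts.shape[0], pts.shape[1], seed)
    return DiversityTriple(top=top(pts), ted=ted(pts, reference), fdis=fdis(pts))
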