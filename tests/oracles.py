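"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and, where possible, the
libraries) used by the package itself: minimum enclosing circles via
Welzl's algorithm, colony confirmation by exhaustive 4-subset enumeration,
Delaunay edges by empty-circumcircle triangle enumeration, and
complete-linkage clustering by naive agglomeration.
"""

from __future__ import annotations

import itertools

import numpy as np


def _circle_two(p, q):
    c = (p + q) / 2.0
    return c, np.hypot(*(p - c))


def _circle_three(p, q, r):
    ax, ay = p
    bx, by = q
    cx, cy = r
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-14:
        return None, np.inf
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
          + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
          + (cx**2 + cy**2) * (bx - ax)) / d
    c = np.array([ux, uy])
    return c, np.hypot(*(p - c))


def minimum_enclosing_circle(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact MEC by checking all 2- and 3-point support sets (small n only)."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n == 0:
        raise ValueError("empty point set")
    if n == 1:
        return pts[0], 0.0
    best_c, best_r = None, np.inf
    eps = 1e-9
    for i, j in itertools.combinations(range(n), 2):
        c, r = _circle_two(pts[i], pts[j])
        if r < best_r and np.all(np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1]) <= r + eps):
            best_c, best_r = c, r
    for i, j, k in itertools.combinations(range(n), 3):
        c, r = _circle_three(pts[i], pts[j], pts[k])
        if c is None:
            continue
        if r < best_r and np.all(np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1]) <= r + eps):
            best_c, best_r = c, r
    return best_c, best_r


def confirmed_by_enumeration(points: np.ndarray, min_cells: int, diameter: float) -> bool:
    """Does some >= min_cells subset fit in a circle of the given diameter?"""
    pts = np.asarray(points, dtype=float)
    if len(pts) < min_cells:
        return False
    for subset in itertools.combinations(range(len(pts)), min_cells):
        _, r = minimum_enclosing_circle(pts[list(subset)])
        if 2.0 * r <= diameter + 1e-9:
            return True
    return False


def delaunay_edges_by_circumcircle(points: np.ndarray) -> set[tuple[int, int]]:
    """Edges of all triangles whose circumcircle is empty of other points."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    edges: set[tuple[int, int]] = set()
    for i, j, k in itertools.combinations(range(n), 3):
        c, r = _circle_three(pts[i], pts[j], pts[k])
        if c is None:
            continue
        others = [m for m in range(n) if m not in (i, j, k)]
        if others:
            d = np.hypot(pts[others, 0] - c[0], pts[others, 1] - c[1])
            if np.any(d < r - 1e-9):
                continue
        for a, b in ((i, j), (j, k), (i, k)):
            edges.add((min(a, b), max(a, b)))
    return edges


def complete_linkage_partition(x: np.ndarray, k: int) -> set[frozenset[int]]:
    """Naive furthest-neighbour agglomeration down to k clusters."""
    x = np.asarray(x, dtype=float)
    clusters: list[set[int]] = [{i} for i in range(len(x))]
    d = np.hypot if x.ndim == 1 else None

    def dist(a: set[int], b: set[int]) -> float:
        return max(np.linalg.norm(x[i] - x[j]) for i in a for j in b)

    while len(clusters) > k:
        best = None
        best_d = np.inf
        for ai, bi in itertools.combinations(range(len(clusters)), 2):
            dd = dist(clusters[ai], clusters[bi])
            if dd < best_d:
                best_d, best = dd, (ai, bi)
        ai, bi = best
        clusters[ai] = clusters[ai] | clusters[bi]
        del clusters[bi]
    return {frozenset(c) for c in clusters}
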