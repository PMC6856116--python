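"""Colony shape statistics: cell long axis and Delaunay inter-cell distance.

Two morphometric descriptors summarise a colony at a chosen frame
(end-of-culture by default):

* the mean **long axis** of its cells — the major-axis length of the
  ellipse with the same normalized second central moments as each cell's
  pixel region;
* the mean **inter-cell distance** — the average edge length of the
  Delaunay triangulation of the cell centres of gravity.

Both are reported in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .colony import Colony
from .detect import DetectedObject


def long_axis(rows: np.ndarray, cols: np.ndarray, pixel_size_um: float = 1.0) -> float:
    """Major-axis length of a pixel region's equivalent ellipse, in um.

    Central second moments of the pixel coordinates are computed with the
    1/12 pixel-extent correction (each pixel is a unit square, not a
    point), matching the common region-properties convention; the long
    axis is ``4 * sqrt(lambda_max)`` where ``lambda_max`` is the largest
    eigenvalue of the second-moment matrix.
    """
    r = np.asarray(rows, dtype=float)
    c = np.asarray(cols, dtype=float)
    if r.size == 0 or r.size != c.size:
        raise ValueError("pixel set must be non-empty with matching row/col arrays")
    rc, cc = r - r.mean(), c - c.mean()
    mu_rr = (rc**2).mean() + 1.0 / 12.0
    mu_cc = (cc**2).mean() + 1.0 / 12.0
    mu_rc = (rc * cc).mean()
    common = (mu_rr + mu_cc) / 2.0
    diff = np.sqrt(((mu_rr - mu_cc) / 2.0) ** 2 + mu_rc**2)
    lam_max = common + diff
    return float(4.0 * np.sqrt(lam_max) * pixel_size_um)


def _collinear_mean_spacing(pts: np.ndarray) -> float:
    """Mean consecutive spacing of (near-)collinear points along their line."""
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    t = np.sort(centered @ vt[0])
    return float(np.diff(t).mean())


def delaunay_edges(points: np.ndarray) -> set[tuple[int, int]]:
    """Unique undirected edges of the Delaunay triangulation."""
    tri = Delaunay(points)
    edges: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            edges.add((min(i, j), max(i, j)))
    return edges


def intercell_distance(centroids_um: np.ndarray) -> float:
    """Mean Delaunay edge length between cell centres of gravity, in um.

    For three or more points in general position the Delaunay
    triangulation is built and the mean length of its unique edges
    returned.  Two points, or a degenerate (collinear) set, fall back to
    the mean of consecutive pairwise distances along the line.
    """
    pts = np.asarray(centroids_um, dtype=float).reshape(-1, 2)
    if len(pts) < 2:
        raise ValueError("at least 2 points required")
    if len(pts) == 2:
        return float(np.hypot(*(pts[1] - pts[0])))
    try:
        edges = delaunay_edges(pts)
    except QhullError:
        return _collinear_mean_spacing(pts)
    lengths = [np.hypot(*(pts[j] - pts[i])) for i, j in sorted(edges)]
    return float(np.mean(lengths))


@dataclass
class MorphometricRecord:
    colony_id: int
    frame_index: int
    mean_long_axis_um: float
    mean_intercell_distance_um: float
    n_cells: int


def colony_morphometrics(
    colony: Colony,
    frame_objects: list[DetectedObject],
    frame_index: int,
    pixel_size_um: float,
) -> MorphometricRecord:
    """Both shape statistics for one colony at one frame.

    ``frame_objects`` must be the frame's living-cell objects in the order
    referenced by ``colony.member_indices_by_frame``.  The colony value of
    each statistic is the mean over member cells (long axis) or over
    Delaunay edges between member centroids (inter-cell distance); with a
    single member the inter-cell distance is reported as NaN.
    """
    if frame_index not in colony.member_indices_by_frame:
        raise ValueError(f"colony {colony.colony_id} has no members at frame {frame_index}")
    idx = colony.member_indices_by_frame[frame_index]
    members = [frame_objects[i] for i in idx]
    axes = [long_axis(o.rows, o.cols, pixel_size_um) for o in members]
    pts = colony.members_by_frame[frame_index]
    dist = intercell_distance(pts) if len(pts) >= 2 else float("nan")
    return MorphometricRecord(
        colony_id=colony.colony_id,
        frame_index=frame_index,
        mean_long_axis_um=float(np.mean(axes)),
        mean_intercell_distance_um=dist,
        n_cells=len(members),
    )
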