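"""Colony identification, merge exclusion and per-colony growth curves.

A colony is a clonal population grown from one founding cell.  It is
*confirmed* once it contains at least ``min_cells`` cells that fit within a
circle of diameter ``colony_diameter_um`` (defaults 4 cells / 320 um, i.e.
80 px at 4 um/px).  Cells are grouped per frame by single-linkage at the
``merge_distance_um`` cutoff (100 um), so distinct groups are at least
100 um apart by construction; colony identity is carried across frames by
member overlap.  When two previously distinct colonies approach within
100 um of each other (their groups fuse), both are flagged *merged* from
that frame onward and excluded from growth-curve output, because their
clonality is lost.

The 320-um rule is treated as a confirmation threshold only: once
confirmed, a colony keeps all of its single-linkage members even after it
outgrows the 320-um circle.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)


@dataclass
class ColonyConfig:
    min_cells: int = 4
    colony_diameter_um: float = 320.0
    merge_distance_um: float = 100.0
    link_distance_um: float = 40.0  # member-overlap gate for colony identity

    def __post_init__(self) -> None:
        if self.min_cells < 2:
            raise ValueError("min_cells must be >= 2")
        if self.colony_diameter_um <= 0 or self.merge_distance_um <= 0:
            raise ValueError("diameters must be positive")


def max_points_in_circle(points: np.ndarray, radius: float, eps: float = 1e-9) -> int:
    """Largest number of points coverable by one circle of given radius.

    Exact O(n^3) search: an optimal covering circle can always be moved so
    that it passes through two of the covered points (or is centred on a
    point when it covers only coincident points), so it suffices to test
    circles centred on each point and on the two centres determined by
    each pair of points closer than one diameter.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n == 0:
        return 0
    centers = [pts]
    d = cdist(pts, pts)
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] <= 2 * radius + eps and d[i, j] > 0:
                mid = (pts[i] + pts[j]) / 2
                half = d[i, j] / 2
                h = np.sqrt(max(radius**2 - half**2, 0.0))
                perp = np.array([-(pts[j, 1] - pts[i, 1]), pts[j, 0] - pts[i, 0]])
                perp /= d[i, j]
                centers.append(np.array([mid + h * perp, mid - h * perp]))
    centers_arr = np.vstack(centers)
    cover = cdist(centers_arr, pts) <= radius + eps
    return int(cover.sum(axis=1).max())


def is_confirmed_colony(centroids_um: np.ndarray, config: ColonyConfig) -> bool:
    """True if >= min_cells of the points fit in a colony-diameter circle."""
    pts = np.asarray(centroids_um, dtype=float)
    if len(pts) < config.min_cells:
        return False
    radius = config.colony_diameter_um / 2.0
    # cheap sufficient test: enough points within `radius` of one member
    d = cdist(pts, pts)
    if (d <= radius).sum(axis=1).max() >= config.min_cells:
        return True
    return max_points_in_circle(pts, radius) >= config.min_cells


@dataclass
class FrameGroup:
    """Single-linkage group of living cells in one frame."""

    indices: np.ndarray  # positions within the frame's living-cell list
    centroids_um: np.ndarray
    confirmed: bool


def group_cells(centroids_um: np.ndarray, config: ColonyConfig) -> list[FrameGroup]:
    """Partition one frame's living-cell centroids into candidate colonies.

    Cells closer than ``merge_distance_um`` (strictly) are linked; the
    connected components of this graph are the groups, so every cell
    belongs to exactly one group and distinct groups are >= 100 um apart.
    A group is a confirmed colony iff some subset of >= ``min_cells``
    members fits within a circle of diameter ``colony_diameter_um``.
    """
    pts = np.asarray(centroids_um, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n == 0:
        return []
    adj = cdist(pts, pts) < config.merge_distance_um
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups = []
    for comp in range(n_comp):
        idx = np.nonzero(labels == comp)[0]
        sub = pts[idx]
        groups.append(
            FrameGroup(indices=idx, centroids_um=sub, confirmed=is_confirmed_colony(sub, config))
        )
    groups.sort(key=lambda g: int(g.indices.min()))
    return groups


@dataclass
class Colony:
    """A tracked (candidate) colony with per-frame membership."""

    colony_id: int
    members_by_frame: dict[int, np.ndarray] = field(default_factory=dict)  # um
    member_indices_by_frame: dict[int, list[int]] = field(default_factory=dict)
    confirmed_frame: int | None = None
    merged: bool = False
    merged_frame: int | None = None
    daily_counts: dict[int, int] = field(default_factory=dict)

    @property
    def confirmed(self) -> bool:
        return self.confirmed_frame is not None

    @property
    def frames(self) -> list[int]:
        return sorted(self.members_by_frame)


def _overlap(group_pts: np.ndarray, prev_pts: np.ndarray, link_um: float) -> int:
    """Members of the group within the link distance of any previous member."""
    if len(group_pts) == 0 or len(prev_pts) == 0:
        return 0
    return int((cdist(group_pts, prev_pts).min(axis=1) <= link_um).sum())


def track_colonies(
    partitions_by_frame: list[list[FrameGroup]],
    config: ColonyConfig,
) -> list[Colony]:
    """Propagate colony identity across frames by member overlap.

    A colony keeps its id while at least one current group member lies
    within ``link_distance_um`` of one of its previous-frame members; a
    colony may own several groups in one frame (a transient chain break —
    e.g. one member missed by detection — does not spawn a new identity).
    If one group overlaps several existing colonies (two colonies have
    come within the single-linkage cutoff of each other), the group's
    members are divided among the claimant colonies by nearest previous
    membership so that the subsequent merge test can see both parties.
    Groups with no overlap found a new colony.  Confirmation is evaluated
    per colony on its own members and latches at the first frame it holds.
    """
    colonies: dict[int, Colony] = {}
    prev_members: dict[int, np.ndarray] = {}
    next_id = 0

    for f, groups in enumerate(partitions_by_frame):
        new_members: dict[int, list[np.ndarray]] = {}
        new_indices: dict[int, list[int]] = {}
        for g in groups:
            claim = [
                cid
                for cid, pts in prev_members.items()
                if _overlap(g.centroids_um, pts, config.link_distance_um) > 0
            ]
            if not claim:
                cid = next_id
                next_id += 1
                colonies[cid] = Colony(colony_id=cid)
                claim = [cid]
            if len(claim) == 1:
                parts = {claim[0]: np.arange(len(g.centroids_um))}
            else:
                # fused group: divide members by nearest previous colony
                dists = np.stack(
                    [cdist(g.centroids_um, prev_members[c]).min(axis=1) for c in claim]
                )
                owner = np.argmin(dists, axis=0)
                parts = {c: np.nonzero(owner == k)[0] for k, c in enumerate(claim)}
            for cid, sel in parts.items():
                if len(sel) == 0:
                    continue
                new_members.setdefault(cid, []).append(g.centroids_um[sel])
                new_indices.setdefault(cid, []).extend(int(g.indices[s]) for s in sel)
        prev_members = {}
        for cid, chunks in new_members.items():
            pts = np.vstack(chunks)
            col = colonies[cid]
            col.members_by_frame[f] = pts
            col.member_indices_by_frame[f] = new_indices[cid]
            prev_members[cid] = pts
            if col.confirmed_frame is None and is_confirmed_colony(pts, config):
                col.confirmed_frame = f
    return sorted(colonies.values(), key=lambda c: c.colony_id)


def detect_merges(colonies: list[Colony], config: ColonyConfig) -> list[Colony]:
    """Flag colony pairs whose closest cells come within the merge distance.

    For every frame and every pair of colonies confirmed by that frame, the
    minimum cross-pair cell distance is computed; if it is strictly less
    than ``merge_distance_um``, both colonies are flagged merged from that
    frame onward (no un-merging).  Merged colonies are excluded from
    growth-curve output.
    """
    all_frames = sorted({f for c in colonies for f in c.members_by_frame})
    for f in all_frames:
        present = [
            c
            for c in colonies
            if f in c.members_by_frame
            and c.confirmed_frame is not None
            and c.confirmed_frame <= f
        ]
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                a, b = present[i], present[j]
                dmin = cdist(a.members_by_frame[f], b.members_by_frame[f]).min()
                if dmin < config.merge_distance_um:
                    for col in (a, b):
                        if not col.merged:
                            col.merged = True
                            col.merged_frame = f
    return colonies


def build_growth_curves(
    colonies: list[Colony],
    day_reference_frames: dict[int, int],
) -> pd.DataFrame:
    """Colony x day matrix of living-cell counts for analysable colonies.

    Rows are confirmed, non-merged colonies ordered by id; column ``day_d``
    holds the number of member cells at day *d*'s reference frame (the last
    frame of the 24-h window).  A colony with no observation at a reference
    frame carries its last known count (with a warning); counts before the
    colony's first observation are backfilled from its first known value.
    """
    days = sorted(day_reference_frames)
    rows = {}
    for col in colonies:
        if not col.confirmed or col.merged:
            continue
        counts: list[float] = []
        for d in days:
            ref = day_reference_frames[d]
            if ref in col.members_by_frame:
                counts.append(len(col.members_by_frame[ref]))
            else:
                earlier = [f for f in col.members_by_frame if f < ref]
                if earlier:
                    carried = len(col.members_by_frame[max(earlier)])
                    warnings.warn(
                        f"colony {col.colony_id}: no observation at day-{d} reference "
                        f"frame {ref}; carrying last known count {carried}"
                    )
                    counts.append(carried)
                else:
                    counts.append(np.nan)  # backfilled below
        arr = np.array(counts, dtype=float)
        if np.isnan(arr).any():
            first = arr[~np.isnan(arr)]
            if len(first) == 0:
                continue
            warnings.warn(
                f"colony {col.colony_id}: backfilling days before first observation"
            )
            arr[np.isnan(arr)] = first[0]
        col.daily_counts = {d: int(v) for d, v in zip(days, arr)}
        rows[col.colony_id] = arr.astype(int)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=[f"day_{d}" for d in days])
    df.index.name = "colony_id"
    return df.sort_index()
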