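"""Temporal linking of detections and persistence-based debris rejection.

Phase-contrast cultures of primary cells contain debris (tissue fragments,
red blood cells) as large as the cells themselves, so noise cannot be
rejected by size.  Living, adherent cells instead stay in essentially the
same position from frame to frame, while debris drifts or tumbles rapidly.
Objects are therefore linked across frames by greedy nearest-neighbour
assignment and a track is labelled a living cell only if it persists — a
run of at least ``min_frames`` consecutive frames with every inter-frame
step at most ``max_step_px``.  Everything else is image noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.spatial.distance import cdist

from .detect import DetectedObject


class TrackLabel(str, Enum):
    LIVING = "living"
    NOISE = "noise"
    UNDECIDED = "undecided"


@dataclass
class CellTrack:
    """A temporally linked chain of detections."""

    track_id: int
    observations: list[tuple[int, DetectedObject]] = field(default_factory=list)
    label: TrackLabel = TrackLabel.UNDECIDED

    def __post_init__(self) -> None:
        frames = [f for f, _ in self.observations]
        if frames != sorted(set(frames)):
            raise ValueError("observation frame indices must be strictly increasing")

    @property
    def frames(self) -> list[int]:
        return [f for f, _ in self.observations]

    @property
    def centroids(self) -> np.ndarray:
        return np.array([o.centroid_xy for _, o in self.observations])

    @property
    def max_step_px(self) -> float:
        c = self.centroids
        if len(c) < 2:
            return 0.0
        return float(np.hypot(*np.diff(c, axis=0).T).max())


@dataclass
class TrackingConfig:
    """Defaults quantify 'same position over several frames': a living cell
    must hold still (steps <= 10 px = 40 um) for 3 consecutive 6-h frames."""

    gate_px: float = 10.0
    min_frames: int = 3
    max_step_px: float = 10.0


def link_objects(
    objects_by_frame: list[list[DetectedObject]], gate_px: float = 10.0
) -> list[CellTrack]:
    """Link per-frame detections into tracks by greedy nearest neighbour.

    For every consecutive frame pair, candidate links (distance <=
    ``gate_px``) are taken in order of increasing distance, ties broken by
    the smaller ``(min_row, min_col)`` of the earlier object; each object
    joins at most one track.  Unmatched objects found in a frame start new
    tracks.  Greedy matching (rather than globally optimal assignment) is
    adequate at colony-assay sparsity; dense fields are a documented
    limitation.
    """
    if gate_px <= 0:
        raise ValueError("gate_px must be positive")
    tracks: list[CellTrack] = []
    open_tracks: list[CellTrack] = []  # tracks whose last observation is in frame f-1

    for f, objects in enumerate(objects_by_frame):
        new_open: list[CellTrack] = []
        claimed = [False] * len(objects)
        if open_tracks and objects:
            prev_xy = np.array([t.observations[-1][1].centroid_xy for t in open_tracks])
            cur_xy = np.array([o.centroid_xy for o in objects])
            d = cdist(prev_xy, cur_xy)
            pairs = [
                (d[i, j], open_tracks[i].observations[-1][1].bbox[:2], i, j)
                for i in range(len(open_tracks))
                for j in range(len(objects))
                if d[i, j] <= gate_px
            ]
            pairs.sort(key=lambda p: (p[0], p[1]))
            used_tracks: set[int] = set()
            for dist, _tie, i, j in pairs:
                if i in used_tracks or claimed[j]:
                    continue
                open_tracks[i].observations.append((f, objects[j]))
                used_tracks.add(i)
                claimed[j] = True
                new_open.append(open_tracks[i])
        for j, obj in enumerate(objects):
            if not claimed[j]:
                t = CellTrack(track_id=len(tracks), observations=[(f, obj)])
                tracks.append(t)
                new_open.append(t)
        open_tracks = new_open
    return tracks


def _has_persistent_run(track: CellTrack, min_frames: int, max_step_px: float) -> bool:
    """True if some run of >= min_frames consecutive frames has all steps small."""
    frames = track.frames
    xy = track.centroids
    run = 1
    for i in range(1, len(frames)):
        consecutive = frames[i] == frames[i - 1] + 1
        step_ok = np.hypot(*(xy[i] - xy[i - 1])) <= max_step_px
        run = run + 1 if (consecutive and step_ok) else 1
        if run >= min_frames:
            return True
    return min_frames <= 1


def classify_tracks(
    tracks: list[CellTrack],
    min_frames: int = 3,
    max_step_px: float = 10.0,
) -> list[CellTrack]:
    """Label each track as a living cell or image noise.

    A track is ``living`` iff it contains at least ``min_frames``
    consecutive observations with every inter-frame centroid displacement
    at most ``max_step_px``; otherwise it is ``noise``.  Teleporting
    debris, whose detections never link into persistent tracks, is thereby
    rejected regardless of its size.  Labels are assigned in place and the
    list is returned for convenience.
    """
    if min_frames < 2:
        raise ValueError("min_frames must be >= 2")
    for t in tracks:
        persistent = _has_persistent_run(t, min_frames, max_step_px)
        t.label = TrackLabel.LIVING if persistent else TrackLabel.NOISE
    return tracks


def living_cells_by_frame(
    tracks: list[CellTrack], n_frames: int
) -> list[list[tuple[int, DetectedObject]]]:
    """Per-frame list of (track_id, object) for living-labelled tracks.

    Cell counting is per frame, not per track: a dividing cell's daughter
    starts a new track, and every observation of a living track counts as
    one cell in its frame (including the track's earliest frames, since
    persistence is judged over the whole sequence).
    """
    out: list[list[tuple[int, DetectedObject]]] = [[] for _ in range(n_frames)]
    for t in tracks:
        if t.label is not TrackLabel.LIVING:
            continue
        for f, obj in t.observations:
            if 0 <= f < n_frames:
                out[f].append((t.track_id, obj))
    return out
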