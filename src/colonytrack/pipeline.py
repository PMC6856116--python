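"""End-to-end pipeline: detection -> tracking -> colonies -> analysis."""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .colony import Colony, build_growth_curves, detect_merges, group_cells, track_colonies
from .detect import DetectedObject, detect_sequence
from .growth import GrowthCurveSet, analyze_growth
from .io import PipelineConfig
from .morphometrics import MorphometricRecord, colony_morphometrics
from .sequence import ImageSequence
from .track import CellTrack, classify_tracks, link_objects, living_cells_by_frame

logger = logging.getLogger(__name__)


@dataclass
class PipelineResults:
    config: PipelineConfig
    objects_by_frame: list[list[DetectedObject]] = field(default_factory=list)
    tracks: list[CellTrack] = field(default_factory=list)
    living_by_frame: list = field(default_factory=list)
    colonies: list[Colony] = field(default_factory=list)
    growth_curves: pd.DataFrame = field(default_factory=pd.DataFrame)
    growth: GrowthCurveSet | None = None
    morphometrics: list[MorphometricRecord] = field(default_factory=list)
    day_reference_frames: dict[int, int] = field(default_factory=dict)
    frames: list[np.ndarray] | None = None


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                logger.error("stage %s failed: %s", name, exc)
                return False
            logger.info("stage %s done in %.1fs", name, time.perf_counter() - self.t0)
            return False

    return _Timer()


def run_pipeline(seq: ImageSequence, config: PipelineConfig) -> PipelineResults:
    """Run the full analysis on an in-memory image sequence.

    Stages: per-frame detection, temporal linking and living/noise
    classification, per-frame colony grouping, colony tracking and merge
    exclusion, daily growth curves, end-of-culture morphometrics, curve
    clustering and day-wise prediction R².
    """
    if len(seq) == 0:
        raise ValueError("no frames")
    results = PipelineResults(config=config, frames=seq.frames)
    px = seq.pixel_size_um

    with _stage("detection"):
        results.objects_by_frame = detect_sequence(seq.frames, config.detection)
        logger.info(
            "detected %d objects over %d frames",
            sum(len(o) for o in results.objects_by_frame),
            len(seq),
        )

    with _stage("tracking"):
        results.tracks = link_objects(results.objects_by_frame, config.tracking.gate_px)
        classify_tracks(
            results.tracks, config.tracking.min_frames, config.tracking.max_step_px
        )
        results.living_by_frame = living_cells_by_frame(results.tracks, len(seq))

    with _stage("colony grouping"):
        partitions = []
        for frame_cells in results.living_by_frame:
            pts_um = np.array(
                [obj.centroid_xy for _tid, obj in frame_cells], dtype=float
            ).reshape(-1, 2) * px
            partitions.append(group_cells(pts_um, config.colony))
        results.colonies = track_colonies(partitions, config.colony)
        detect_merges(results.colonies, config.colony)
        logger.info(
            "%d colonies tracked, %d confirmed, %d merged",
            len(results.colonies),
            sum(c.confirmed for c in results.colonies),
            sum(c.merged for c in results.colonies),
        )

    with _stage("growth curves"):
        n_days = max(1, int(seq.timestamps[-1] // 24))
        results.day_reference_frames = {
            d: seq.day_reference_frame(d) for d in range(1, n_days + 1)
        }
        results.growth_curves = build_growth_curves(
            results.colonies, results.day_reference_frames
        )
        if results.growth_curves.empty:
            warnings.warn("no confirmed, non-merged colonies: growth-curve table is empty")

    with _stage("morphometrics"):
        final_ref = results.day_reference_frames[max(results.day_reference_frames)]
        living_objs = [
            [obj for _tid, obj in frame_cells] for frame_cells in results.living_by_frame
        ]
        for col in results.colonies:
            if not col.confirmed or col.merged:
                continue
            frame = final_ref if final_ref in col.members_by_frame else (
                col.frames[-1] if col.frames else None
            )
            if frame is None:
                continue
            results.morphometrics.append(
                colony_morphometrics(col, living_objs[frame], frame, px)
            )

    with _stage("growth analysis"):
        if not results.growth_curves.empty:
            k = min(config.k_groups, len(results.growth_curves))
            if k < config.k_groups:
                warnings.warn(
                    f"k_groups reduced from {config.k_groups} to {k} "
                    "(fewer colonies than groups)"
                )
            results.growth = analyze_growth(results.growth_curves, k_groups=k)
    return results
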