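"""Self-contained benchmark studies on synthetic ground truth.

Two studies quantify the pipeline end to end:

* :func:`end_to_end_study` — render the default 20-colony, 14-day
  sequence, run the full pipeline, and score detection
  (precision/recall against ground truth at an 8-px match radius),
  debris rejection, growth-curve recovery (fraction of colony-by-day
  entries equal to the simulator truth) and the regression agreement of
  final-day counts.
* :func:`prediction_study` — simulate a 140-colony growth-curve cohort
  and measure how well each culture day's counts predict the final-day
  counts (OLS R² per day), plus the complete-linkage classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .growth import CountValidation, predict_day14, validate_counts
from .io import PipelineConfig
from .pipeline import PipelineResults, run_pipeline
from .simulate import GroundTruth, SimulationConfig, render_sequence, simulate_ground_truth, simulate_growth_curves
from .track import TrackLabel

MATCH_RADIUS_PX = 8.0


@dataclass
class EndToEndReport:
    mean_precision: float
    min_precision: float
    mean_recall: float
    min_recall: float
    n_living_debris_tracks: int
    n_living_tracks: int
    growth_matrix_agreement: float
    n_matrix_entries: int
    validation: CountValidation
    n_colonies_reported: int
    colony_matching: dict[int, int] = field(default_factory=dict)


def detection_scores(
    results: PipelineResults, truth: GroundTruth
) -> tuple[list[float], list[float]]:
    """Per-frame detection precision and recall against ground truth.

    Recall: true cells matched one-to-one to detections within the match
    radius.  Precision: detections near any true object — debris included,
    since debris is a real image object that detection is expected to find
    and tracking to reject.
    """
    precisions, recalls = [], []
    for f, objects in enumerate(results.objects_by_frame):
        det = np.array([o.centroid_xy for o in objects]).reshape(-1, 2)
        cells = np.array(
            [[c.x_px, c.y_px] for c in truth.cells_by_frame[f]]
        ).reshape(-1, 2)
        debris = np.array(
            [[d.x_px, d.y_px] for d in truth.debris_by_frame[f]]
        ).reshape(-1, 2)
        if len(cells) == 0:
            continue
        if len(det) == 0:
            recalls.append(0.0)
            precisions.append(1.0)
            continue
        d = cdist(det, cells)
        ri, ci = linear_sum_assignment(d)
        recalls.append(float((d[ri, ci] <= MATCH_RADIUS_PX).sum() / len(cells)))
        everything = np.vstack([cells, debris])
        precisions.append(
            float((cdist(det, everything).min(axis=1) <= MATCH_RADIUS_PX).mean())
        )
    return precisions, recalls


def count_living_debris_tracks(results: PipelineResults, truth: GroundTruth) -> tuple[int, int]:
    """Living tracks that follow debris rather than a true cell.

    A living track is attributed to debris when the majority of its
    observations lie within the match radius of a debris position while
    being farther than the match radius from every true cell.
    """
    n_living = 0
    n_debris = 0
    for t in results.tracks:
        if t.label is not TrackLabel.LIVING:
            continue
        n_living += 1
        debris_only = 0
        for f, obj in t.observations:
            xy = np.array([obj.centroid_xy])
            cells = np.array(
                [[c.x_px, c.y_px] for c in truth.cells_by_frame[f]]
            ).reshape(-1, 2)
            debris = np.array(
                [[d.x_px, d.y_px] for d in truth.debris_by_frame[f]]
            ).reshape(-1, 2)
            near_cell = len(cells) > 0 and cdist(xy, cells).min() <= MATCH_RADIUS_PX
            near_debris = len(debris) > 0 and cdist(xy, debris).min() <= MATCH_RADIUS_PX
            if near_debris and not near_cell:
                debris_only += 1
        if debris_only > len(t.observations) / 2:
            n_debris += 1
    return n_debris, n_living


def match_colonies(
    results: PipelineResults, truth: GroundTruth, pixel_size_um: float
) -> dict[int, int]:
    """Map reported (confirmed, non-merged) colonies to truth colonies.

    Matching is by proximity of the colony's earliest observed member
    centroid to the truth founder positions.
    """
    mapping: dict[int, int] = {}
    seed_ids = sorted(truth.seed_positions)
    seeds = np.array([truth.seed_positions[i] for i in seed_ids])
    for col in results.colonies:
        if not col.confirmed or col.merged:
            continue
        f0 = col.frames[0]
        cent_px = col.members_by_frame[f0].mean(axis=0) / pixel_size_um
        d = np.hypot(seeds[:, 0] - cent_px[0], seeds[:, 1] - cent_px[1])
        mapping[col.colony_id] = seed_ids[int(np.argmin(d))]
    return mapping


def end_to_end_study(
    seed: int = 1,
    sim_config: SimulationConfig | None = None,
    pipeline_config: PipelineConfig | None = None,
) -> tuple[EndToEndReport, PipelineResults, GroundTruth]:
    """Run the default rendered-sequence benchmark and score it."""
    sim = sim_config or SimulationConfig(seed=seed)
    cfg = pipeline_config or PipelineConfig(seed=seed)
    truth = simulate_ground_truth(sim)
    seq = render_sequence(truth, sim)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = run_pipeline(seq, cfg)

    precisions, recalls = detection_scores(results, truth)
    n_debris, n_living = count_living_debris_tracks(results, truth)
    mapping = match_colonies(results, truth, sim.pixel_size_um)

    match = total = 0
    det_final, tru_final = [], []
    for cid, tid in mapping.items():
        det = results.growth_curves.loc[cid].to_numpy()
        tru = truth.daily_counts[tid]
        eq = det == tru
        match += int(eq.sum())
        total += int(eq.size)
        det_final.append(det[-1])
        tru_final.append(tru[-1])
    validation = validate_counts(np.array(det_final), np.array(tru_final))

    report = EndToEndReport(
        mean_precision=float(np.mean(precisions)),
        min_precision=float(np.min(precisions)),
        mean_recall=float(np.mean(recalls)),
        min_recall=float(np.min(recalls)),
        n_living_debris_tracks=n_debris,
        n_living_tracks=n_living,
        growth_matrix_agreement=match / total if total else float("nan"),
        n_matrix_entries=total,
        validation=validation,
        n_colonies_reported=len(mapping),
        colony_matching=mapping,
    )
    return report, results, truth


def prediction_study(
    n_colonies: int = 140, seed: int = 1, k_groups: int = 7
) -> tuple[dict[int, float], pd.DataFrame, np.ndarray]:
    """Day-wise prediction R² and clustering for a simulated cohort."""
    from .growth import cluster_curves

    cfg = SimulationConfig(n_colonies=n_colonies, seed=seed)
    matrix, _ = simulate_growth_curves(cfg)
    counts = pd.DataFrame(
        matrix, columns=[f"day_{d}" for d in range(1, cfg.duration_days + 1)]
    )
    counts.index.name = "colony_id"
    r2 = predict_day14(counts)
    labels, _ = cluster_curves(np.sqrt(matrix), k_groups=k_groups)
    return r2, counts, labels
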