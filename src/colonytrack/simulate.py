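"""Ground-truthed synthetic time-lapse data for colony-growth analysis.

The generator emulates a low-density colony-forming assay of fibroblast-like
mesenchymal stromal cells imaged by phase-contrast microscopy: single
founder cells seeded sparsely, dividing over 14 days with one frame every
6 hours.  Three growth archetypes (``large``, ``medium``, ``small``) mimic
the heterogeneous colony-forming ability seen in primary cultures; each
colony grows as a pure-birth (Yule) process with an archetype-specific mean
cell-cycle time after an initial lag.

Rendered frames reproduce the two cues a phase-contrast detector relies on:
a dark cell interior and a bright halo rim, on top of a smooth low-frequency
background-brightness gradient.  Tissue debris — blobs the size of cells
that jump to an unrelated position every frame — is included so that
temporal-persistence filtering can be exercised: debris cannot be rejected
by size alone.

Everything is deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import ellipse

from .sequence import ImageSequence

ARCHETYPES = ("large", "medium", "small")


class ConfigurationError(ValueError):
    """Raised for invalid simulation or pipeline configuration."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic colony-forming assay.

    Defaults follow the imaging protocol the package targets (one frame
    every 6 h for 14 days, 4 um/px whole-well scans) and cell-biology
    values realistic for primary synovial MSCs: mean exponential
    cell-cycle times of 64/96/168 h for the large/medium/small archetypes
    (population doubling times of roughly 1.8/2.8/4.9 days) and lags of
    0.5/1/2 days before the first division.
    """

    n_colonies: int = 20
    seed: int = 0
    frame_interval_h: float = 6.0
    duration_days: int = 14
    pixel_size_um: float = 4.0
    frame_shape: tuple[int, int] = (1024, 1024)
    group_mix: dict[str, float] = field(
        default_factory=lambda: {"large": 0.2, "medium": 0.5, "small": 0.3}
    )
    division_interval_h: dict[str, float] = field(
        default_factory=lambda: {"large": 64.0, "medium": 96.0, "small": 168.0}
    )
    lag_h: dict[str, float] = field(
        default_factory=lambda: {"large": 12.0, "medium": 24.0, "small": 48.0}
    )
    deterministic_divisions: bool = False
    debris_count: int = 10
    debris_jump_px: float = 20.0
    background_level: float = 128.0
    background_gradient_amplitude: float = 30.0
    cell_long_axis_um: float = 40.0
    cell_interior_contrast: float = 30.0
    cell_rim_contrast: float = 40.0
    noise_sigma: float = 2.0
    brownian_jitter_px: float = 0.0
    colony_margin_px: float = 100.0
    min_colony_separation_px: float = 200.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if abs(sum(self.group_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("group_mix proportions must sum to 1")
        if any(p < 0 for p in self.group_mix.values()):
            raise ConfigurationError("group_mix proportions must be non-negative")
        if set(self.group_mix) - set(ARCHETYPES):
            raise ConfigurationError(f"unknown archetypes in group_mix: {self.group_mix}")
        if self.duration_days < 1:
            raise ConfigurationError("duration_days must be >= 1")
        if self.frame_interval_h <= 0 or 24.0 % self.frame_interval_h != 0:
            raise ConfigurationError("frame_interval_h must divide 24")
        for name in ("n_colonies", "debris_count"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be positive")

    @property
    def n_frames(self) -> int:
        """Frames at 0, dt, 2*dt, ... through the end of the last day."""
        return int(self.duration_days * 24 / self.frame_interval_h) + 1

    @property
    def frames_per_day(self) -> int:
        return int(24 / self.frame_interval_h)

    def frame_time_h(self, frame_index: int) -> float:
        return frame_index * self.frame_interval_h

    def day_reference_frame(self, day: int) -> int:
        """Last frame within culture day ``day`` (index ``4*d`` at 6-h steps)."""
        return self.frames_per_day * day


@dataclass
class CellRecord:
    """One true cell in one frame."""

    cell_id: int
    colony_id: int
    x_px: float
    y_px: float
    major_axis_px: float
    minor_axis_px: float
    orientation_rad: float


@dataclass
class DebrisRecord:
    debris_id: int
    x_px: float
    y_px: float
    major_axis_px: float
    minor_axis_px: float
    orientation_rad: float


@dataclass
class GroundTruth:
    """Complete per-frame truth for a rendered synthetic sequence."""

    config: SimulationConfig
    cells_by_frame: list[list[CellRecord]]
    debris_by_frame: list[list[DebrisRecord]]
    daily_counts: dict[int, np.ndarray]  # colony_id -> counts for days 1..duration
    archetypes: dict[int, str]  # colony_id -> archetype
    seed_positions: dict[int, tuple[float, float]]  # colony_id -> founder (x, y) px
    merge_events: list[tuple[int, int, int]]  # (frame, colony_a, colony_b)

    def counts_matrix(self) -> np.ndarray:
        """Colony x day matrix of true counts, ordered by colony_id."""
        ids = sorted(self.daily_counts)
        return np.array([self.daily_counts[i] for i in ids], dtype=int)


def _division_times(
    rng: np.random.Generator, tau: float, lag: float, t_end: float, deterministic: bool
) -> list[float]:
    """Birth times (h) of all cells in one colony, founder excluded.

    Pure-birth process: the founder appears at t=0; after a colony lag,
    every cell divides independently with exponential waiting times of
    mean ``tau`` (or exactly every ``tau`` in deterministic mode).
    """
    if not np.isfinite(tau):
        return []
    if deterministic:
        births: list[float] = []
        n = 1
        t = lag + tau
        while t <= t_end + 1e-9:
            births.extend([t] * n)  # every cell divides synchronously
            n *= 2
            t += tau
        return births
    # event queue of per-cell next division times
    births = []
    heap = [lag + rng.exponential(tau)]
    while heap:
        t = heapq.heappop(heap)
        if t > t_end:
            continue
        births.append(t)
        heapq.heappush(heap, t + rng.exponential(tau))  # mother divides again
        heapq.heappush(heap, t + rng.exponential(tau))  # daughter's first division
    return sorted(births)


def _counts_at(births: list[float], times: np.ndarray) -> np.ndarray:
    """Colony size at each time: 1 founder + births at or before t."""
    b = np.asarray(births, dtype=float)
    return 1 + np.searchsorted(np.sort(b), times, side="right") if len(b) else np.ones(
        len(times), dtype=int
    )


def _assign_archetypes(rng: np.random.Generator, config: SimulationConfig) -> list[str]:
    names = list(config.group_mix)
    probs = np.array([config.group_mix[n] for n in names], dtype=float)
    return list(rng.choice(names, size=config.n_colonies, p=probs))


def simulate_growth_curves(config: SimulationConfig) -> tuple[np.ndarray, list[str]]:
    """Simulate per-colony daily cell counts without rendering images.

    Returns a ``(n_colonies, duration_days)`` integer matrix of colony
    sizes at each day's reference frame, plus the archetype label of each
    colony.  This is the fast path used for curve-level analyses (e.g. a
    140-colony clustering study); the spatial simulator
    :func:`simulate_ground_truth` uses the identical division model.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    archetypes = _assign_archetypes(rng, config)
    t_end = config.duration_days * 24.0
    day_times = np.arange(1, config.duration_days + 1) * 24.0
    rows = []
    for arch in archetypes:
        tau = config.division_interval_h[arch]
        lag = (
            config.lag_h[arch]
            if config.deterministic_divisions
            else rng.exponential(config.lag_h[arch])
            if config.lag_h[arch] > 0
            else 0.0
        )
        births = _division_times(rng, tau, lag, t_end, config.deterministic_divisions)
        rows.append(_counts_at(births, day_times))
    matrix = np.array(rows, dtype=int)
    return matrix, archetypes


def _seed_positions(rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    """Founder positions with an edge margin and a minimum pairwise spacing."""
    h, w = config.frame_shape
    m = min(config.colony_margin_px, 0.15 * min(h, w))
    sep = config.min_colony_separation_px
    while sep >= 1.0:
        pts: list[np.ndarray] = []
        for _ in range(config.n_colonies):
            for _attempt in range(2000):
                p = rng.uniform([m, m], [w - m, h - m])
                if all(np.hypot(*(p - q)) >= sep for q in pts):
                    pts.append(p)
                    break
            else:
                break
        if len(pts) == config.n_colonies:
            if sep < config.min_colony_separation_px:
                warnings.warn(
                    f"colony seed separation relaxed to {sep:.0f} px to fit "
                    f"{config.n_colonies} colonies in {config.frame_shape}"
                )
            return np.array(pts)
        sep *= 0.8
    raise ConfigurationError(
        "could not place colony seeds; lower n_colonies or enlarge the frame"
    )


def _place_daughter(
    rng: np.random.Generator,
    parent_xy: np.ndarray,
    others: np.ndarray,
    spacing_px: float,
) -> np.ndarray:
    """Daughter position near the parent, preferring the least crowded angle.

    Cells are physical, contact-inhibited objects: a daughter keeps a
    hard-core separation (~0.65 of the nominal spacing) from every
    existing cell, moving outward in steps when the ring around the
    parent is full — so colonies stay contiguous monolayers rather than
    stacking cells.
    """
    # clipped so daughters always stay in contact range of the colony
    dist = spacing_px * np.clip(rng.lognormal(mean=0.0, sigma=0.15), 0.75, 1.2)
    hard_core = 0.65 * spacing_px
    best: np.ndarray | None = None
    best_d = -np.inf
    for _ in range(8):
        angles = rng.uniform(0, 2 * np.pi, size=12)
        cands = parent_xy + dist * np.stack([np.cos(angles), np.sin(angles)], axis=1)
        if len(others) == 0:
            return cands[0]
        d = np.hypot(
            cands[:, None, 0] - others[None, :, 0], cands[:, None, 1] - others[None, :, 1]
        ).min(axis=1)
        k = int(np.argmax(d))
        if d[k] > best_d:
            best, best_d = cands[k], d[k]
        if best_d >= hard_core:
            return best
        dist *= 1.15  # ring is crowded: settle farther out
    return best


def simulate_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Spatial simulation of colony formation, ready for rendering.

    Each founder is placed with a margin from the frame edge and a minimum
    spacing between colonies; daughters appear roughly 1.8 cell diameters
    from their mother at the least crowded of several candidate angles,
    which yields contiguous but mostly non-overlapping colonies.  Debris
    positions are resampled independently every frame (teleporting), with
    a per-frame displacement of at least ``debris_jump_px`` enforced.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    archetypes = _assign_archetypes(rng, config)
    seeds = _seed_positions(rng, config) if config.n_colonies else np.zeros((0, 2))
    t_end = config.duration_days * 24.0
    px = config.pixel_size_um
    axis_px = config.cell_long_axis_um / px  # mean long axis in px
    spacing_px = 1.8 * axis_px

    h, w = config.frame_shape

    def draw_axes() -> tuple[float, float, float]:
        major = axis_px * rng.lognormal(0.0, 0.15)
        minor = major * rng.uniform(0.45, 0.7)
        return major, minor, rng.uniform(0, np.pi)

    # Per-colony cell list: (birth_time, x, y, major, minor, orient)
    cells_by_colony: list[list[tuple[float, float, float, float, float, float]]] = []
    for cid in range(config.n_colonies):
        tau = config.division_interval_h[archetypes[cid]]
        mean_lag = config.lag_h[archetypes[cid]]
        lag = (
            mean_lag
            if config.deterministic_divisions
            else rng.exponential(mean_lag)
            if mean_lag > 0
            else 0.0
        )
        births = _division_times(rng, tau, lag, t_end, config.deterministic_divisions)
        maj, mino, ori = draw_axes()
        cells = [(0.0, seeds[cid, 0], seeds[cid, 1], maj, mino, ori)]
        for bt in births:
            # mother chosen uniformly among cells alive at the birth time
            mother = cells[int(rng.integers(len(cells)))]
            others = np.array([[c[1], c[2]] for c in cells])
            pos = _place_daughter(rng, np.array(mother[1:3]), others, spacing_px)
            maj, mino, ori = draw_axes()
            cells.append((bt, pos[0], pos[1], maj, mino, ori))
        cells_by_colony.append(cells)

    # Debris geometry fixed per debris, position resampled per frame.
    debris_axes = [draw_axes() for _ in range(config.debris_count)]

    n_frames = config.n_frames
    cells_by_frame: list[list[CellRecord]] = []
    debris_by_frame: list[list[DebrisRecord]] = []
    next_cell_id = 0
    cell_ids: dict[tuple[int, int], int] = {}  # (colony, index within colony) -> id
    prev_debris = np.full((config.debris_count, 2), np.nan)
    jitter = config.brownian_jitter_px

    for f in range(n_frames):
        t = config.frame_time_h(f)
        frame_cells: list[CellRecord] = []
        for cid, cells in enumerate(cells_by_colony):
            for j, (bt, x, y, maj, mino, ori) in enumerate(cells):
                if bt > t:
                    continue
                key = (cid, j)
                if key not in cell_ids:
                    cell_ids[key] = next_cell_id
                    next_cell_id += 1
                if jitter > 0:
                    x = x + rng.normal(0, jitter)
                    y = y + rng.normal(0, jitter)
                frame_cells.append(
                    CellRecord(cell_ids[key], cid, x, y, maj, mino, ori)
                )
        cells_by_frame.append(frame_cells)

        frame_debris: list[DebrisRecord] = []
        for k in range(config.debris_count):
            for _ in range(1000):
                p = rng.uniform([0, 0], [w, h])
                if np.isnan(prev_debris[k, 0]) or np.hypot(
                    *(p - prev_debris[k])
                ) >= config.debris_jump_px:
                    break
            prev_debris[k] = p
            maj, mino, ori = debris_axes[k]
            frame_debris.append(DebrisRecord(k, p[0], p[1], maj, mino, ori))
        debris_by_frame.append(frame_debris)

    # Daily true counts: distinct cells of the colony present in the day-d
    # reference frame.
    daily_counts: dict[int, np.ndarray] = {}
    days = np.arange(1, config.duration_days + 1)
    for cid, cells in enumerate(cells_by_colony):
        births = np.sort([c[0] for c in cells])
        daily_counts[cid] = np.searchsorted(births, days * 24.0, side="right").astype(int)

    merge_events = _true_merge_events(cells_by_frame, config)
    seed_positions = {cid: (seeds[cid, 0], seeds[cid, 1]) for cid in range(config.n_colonies)}
    return GroundTruth(
        config=config,
        cells_by_frame=cells_by_frame,
        debris_by_frame=debris_by_frame,
        daily_counts=daily_counts,
        archetypes={cid: a for cid, a in enumerate(archetypes)},
        seed_positions=seed_positions,
        merge_events=merge_events,
    )


def _true_merge_events(
    cells_by_frame: list[list[CellRecord]],
    config: SimulationConfig,
    merge_distance_um: float = 100.0,
) -> list[tuple[int, int, int]]:
    """First frame at which each colony pair comes within the merge distance."""
    events: list[tuple[int, int, int]] = []
    seen: set[tuple[int, int]] = set()
    limit_px = merge_distance_um / config.pixel_size_um
    for f, cells in enumerate(cells_by_frame):
        if not cells:
            continue
        xy = np.array([[c.x_px, c.y_px] for c in cells])
        cid = np.array([c.colony_id for c in cells])
        for a in np.unique(cid):
            for b in np.unique(cid):
                if b <= a or (a, b) in seen:
                    continue
                da = xy[cid == a]
                db = xy[cid == b]
                d = np.hypot(da[:, None, 0] - db[None, :, 0], da[:, None, 1] - db[None, :, 1])
                if d.min() < limit_px:
                    seen.add((int(a), int(b)))
                    events.append((f, int(a), int(b)))
    return events


def _background(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-frequency illumination field, constant across frames."""
    h, w = config.frame_shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    theta = rng.uniform(0, 2 * np.pi)
    phase_x, phase_y = rng.uniform(0, 2 * np.pi, size=2)
    a = config.background_gradient_amplitude
    plane = (xx / w) * np.cos(theta) + (yy / h) * np.sin(theta)
    wave = 0.5 * (
        np.sin(2 * np.pi * xx / w + phase_x) + np.sin(2 * np.pi * yy / h + phase_y)
    )
    field_ = 0.6 * plane + 0.4 * 0.5 * wave
    field_ -= field_.mean()
    peak = np.abs(field_).max()
    if peak > 0:
        field_ *= (a / 2) / peak  # amplitude a peak-to-peak
    return config.background_level + field_


def _blob_masks(
    shape: tuple[int, int],
    blobs: list,
    clipped: list[bool],
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Pixel coordinates of all interiors and all halo rims of the blobs.

    Interiors of all cells are collected first and rims second so that the
    bright halo of every cell stays visible on top of any neighbouring
    interior — in phase contrast the halation follows each cell's edge
    even where cells touch.
    """
    h, w = shape
    int_idx: list[np.ndarray] = []
    rim_idx: list[np.ndarray] = []
    for b in blobs:
        a_ax, b_ax = b.major_axis_px / 2.0, b.minor_axis_px / 2.0
        rr_o, cc_o = ellipse(b.y_px, b.x_px, a_ax + 2, b_ax + 2, rotation=b.orientation_rad)
        ok_o = (rr_o >= 0) & (rr_o < h) & (cc_o >= 0) & (cc_o < w)
        if not ok_o.all():
            clipped[0] = True
        rr_i, cc_i = ellipse(b.y_px, b.x_px, a_ax, b_ax, rotation=b.orientation_rad)
        ok_i = (rr_i >= 0) & (rr_i < h) & (cc_i >= 0) & (cc_i < w)
        own = rr_i[ok_i] * w + cc_i[ok_i]
        outer = rr_o[ok_o] * w + cc_o[ok_o]
        int_idx.append(own)
        rim_idx.append(np.setdiff1d(outer, own))  # ring: outer minus own interior
    cat = lambda parts: (  # noqa: E731
        np.concatenate(parts) if parts else np.empty(0, dtype=int)
    )
    interior = np.unique(cat(int_idx))
    rims = np.unique(cat(rim_idx))
    return (interior // w, interior % w), (rims // w, rims % w)


def render_sequence(truth: GroundTruth, config: SimulationConfig | None = None) -> ImageSequence:
    """Render a ground-truth simulation as 8-bit phase-contrast-like frames.

    Each cell (and debris blob) is an ellipse whose interior sits
    ``cell_interior_contrast`` gray levels below the local background and
    whose ~2 px rim sits ``cell_rim_contrast`` levels above it — the halo
    cue of phase-contrast imaging.  A static low-frequency brightness
    gradient and i.i.d. Gaussian pixel noise are added, then the frame is
    clipped to uint8.  Rendering is deterministic given the config seed.
    """
    config = config or truth.config
    if len(truth.cells_by_frame) < config.n_frames:
        raise ValueError("ground truth does not cover the configured duration")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    bg = _background(config, rng)
    frames = []
    clipped = [False]
    for f in range(config.n_frames):
        img = bg.copy()
        blobs = list(truth.cells_by_frame[f]) + list(truth.debris_by_frame[f])
        (ir, ic), (rr, rc) = _blob_masks(img.shape, blobs, clipped)
        img[ir, ic] = bg[ir, ic] - config.cell_interior_contrast
        img[rr, rc] = bg[rr, rc] + config.cell_rim_contrast  # halos drawn on top
        if config.noise_sigma > 0:
            img = img + rng.normal(0, config.noise_sigma, size=img.shape)
        frames.append(np.clip(img, 0, 255).astype(np.uint8))
    if clipped[0]:
        warnings.warn("some objects extended beyond the frame and were clipped")
    return ImageSequence(
        frames=frames,
        pixel_size_um=config.pixel_size_um,
        frame_interval_h=config.frame_interval_h,
    )
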