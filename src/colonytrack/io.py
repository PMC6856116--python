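"""File I/O and configuration for the analysis pipeline.

Input sequences are multi-page TIFFs or directories of lexically ordered
TIFF/PNG frames (8/16-bit grayscale; RGB is averaged to grayscale with a
warning).  Results are written as plain CSV tables plus a JSON run
manifest; optional per-frame PNG overlays colour each colony consistently
across frames.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .colony import ColonyConfig
from .detect import DetectionConfig, ThresholdMethod
from .sequence import ImageSequence
from .track import TrackingConfig

_FRAME_SUFFIXES = (".tif", ".tiff", ".png")


@dataclass
class PipelineConfig:
    """Complete, serialisable configuration of one pipeline run."""

    input_path: str = ""
    output_dir: str = "colonytrack_out"
    pixel_size_um: float = 4.0
    frame_interval_h: float = 6.0
    seed: int = 0
    k_groups: int = 7
    write_overlays: bool = False
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    colony: ColonyConfig = field(default_factory=ColonyConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["detection"]["threshold_method"] = ThresholdMethod(
            self.detection.threshold_method
        ).value
        return d

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        det = dict(d.pop("detection", {}))
        if "threshold_method" in det:
            det["threshold_method"] = ThresholdMethod(det["threshold_method"])
        trk = dict(d.pop("tracking", {}))
        col = dict(d.pop("colony", {}))
        return cls(
            detection=DetectionConfig(**det),
            tracking=TrackingConfig(**trk),
            colony=ColonyConfig(**col),
            **d,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _to_grayscale(arr: np.ndarray, name: str) -> np.ndarray:
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        warnings.warn(f"{name}: RGB input converted to grayscale by channel mean")
        return arr[..., :3].mean(axis=-1).astype(arr.dtype)
    if arr.ndim != 2:
        raise ValueError(f"{name}: expected 2-D grayscale image, got shape {arr.shape}")
    return arr


def read_sequence(
    path: str | Path,
    pixel_size_um: float = 4.0,
    frame_interval_h: float = 6.0,
) -> ImageSequence:
    """Load a time-lapse sequence from a multi-page TIFF or a frame directory.

    Directory frames are taken in lexical filename order; multi-page TIFF
    frames in page order.  16-bit data is preserved.  Physical metadata
    comes from the arguments (config overrides any file metadata).
    """
    p = Path(path)
    frames: list[np.ndarray] = []
    if p.is_dir():
        files = sorted(f for f in p.iterdir() if f.suffix.lower() in _FRAME_SUFFIXES)
        if not files:
            raise ValueError(f"no TIFF/PNG frames found in {p}")
        for f in files:
            try:
                arr = tifffile.imread(f) if f.suffix.lower() in (".tif", ".tiff") else iio.imread(f)
            except Exception as exc:  # noqa: BLE001 - report offending file
                raise ValueError(f"unreadable frame {f}: {exc}") from exc
            frames.append(_to_grayscale(np.asarray(arr), f.name))
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            offender = files[[f.shape for f in frames].index(sorted(shapes)[1])]
            raise ValueError(f"mixed frame shapes {sorted(shapes)}; offending file: {offender}")
    else:
        try:
            stack = tifffile.imread(p)
        except Exception as exc:  # noqa: BLE001
            raise ValueError(f"unreadable file {p}: {exc}") from exc
        stack = np.asarray(stack)
        if stack.ndim == 2:
            stack = stack[None]
        frames = [_to_grayscale(fr, f"{p.name}[{i}]") for i, fr in enumerate(stack)]
    return ImageSequence(
        frames=frames, pixel_size_um=pixel_size_um, frame_interval_h=frame_interval_h
    )


def write_sequence(seq: ImageSequence, path: str | Path) -> None:
    """Write a sequence as a multi-page TIFF."""
    tifffile.imwrite(Path(path), np.stack(seq.frames))


def colony_color(colony_id: int) -> tuple[int, int, int]:
    """Stable, saturated RGB colour derived from the colony id by hashing."""
    h = hashlib.md5(str(colony_id).encode()).digest()
    rgb = np.array(h[:3], dtype=float)
    rgb = 64 + (rgb / 255.0) * 191  # keep colours bright enough to see
    return tuple(int(v) for v in rgb)


def render_overlay(frame: np.ndarray, colonies, frame_index: int, pixel_size_um: float) -> np.ndarray:
    """RGB overlay of one frame with colony members circled and numbered."""
    from PIL import Image, ImageDraw

    g = frame.astype(float)
    g = (255 * (g - g.min()) / max(np.ptp(g), 1)).astype(np.uint8)
    img = Image.fromarray(np.stack([g] * 3, axis=-1))
    draw = ImageDraw.Draw(img)
    for col in colonies:
        if frame_index not in col.members_by_frame:
            continue
        color = colony_color(col.colony_id)
        pts_px = col.members_by_frame[frame_index] / pixel_size_um
        for x, y in pts_px:
            draw.ellipse([x - 6, y - 6, x + 6, y + 6], outline=color, width=2)
        cx, cy = pts_px.mean(axis=0)
        draw.text((cx + 8, cy + 8), str(col.colony_id), fill=color)
    return np.asarray(img)


def write_outputs(results, output_dir: str | Path) -> dict[str, Path]:
    """Write all result tables, the run manifest and optional overlays.

    Returns a mapping from logical table name to the written path.  Merged
    colonies appear in ``colonies.csv`` but are excluded from
    ``growth_curves.csv``.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not out.is_dir():
        raise ValueError(f"output directory {out} is not writable")
    paths: dict[str, Path] = {}

    obj_rows = [
        {
            "frame_index": o.frame_index,
            "x_px": o.centroid_xy[0],
            "y_px": o.centroid_xy[1],
            "area_px": o.area_px,
            "min_row": o.bbox[0],
            "min_col": o.bbox[1],
            "max_row": o.bbox[2],
            "max_col": o.bbox[3],
        }
        for frame in results.objects_by_frame
        for o in frame
    ]
    paths["objects"] = out / "objects.csv"
    pd.DataFrame(obj_rows).to_csv(paths["objects"], index=False)

    trk_rows = [
        {
            "track_id": t.track_id,
            "label": t.label.value,
            "n_observations": len(t.observations),
            "first_frame": t.frames[0],
            "last_frame": t.frames[-1],
            "max_step_px": t.max_step_px,
        }
        for t in results.tracks
    ]
    paths["tracks"] = out / "tracks.csv"
    pd.DataFrame(trk_rows).to_csv(paths["tracks"], index=False)

    col_rows = [
        {
            "colony_id": c.colony_id,
            "confirmed_frame": c.confirmed_frame,
            "merged": c.merged,
            "merged_frame": c.merged_frame,
            "first_frame": c.frames[0] if c.frames else None,
            "last_frame": c.frames[-1] if c.frames else None,
        }
        for c in results.colonies
    ]
    paths["colonies"] = out / "colonies.csv"
    pd.DataFrame(col_rows).to_csv(paths["colonies"], index=False)

    paths["growth_curves"] = out / "growth_curves.csv"
    results.growth_curves.to_csv(paths["growth_curves"])

    labels = results.growth.cluster_labels if results.growth is not None else None
    paths["cluster_labels"] = out / "cluster_labels.csv"
    (labels if labels is not None else pd.Series(dtype=int, name="group")).rename(
        "group"
    ).to_frame().rename_axis("colony_id").to_csv(paths["cluster_labels"])

    morph_rows = [dataclasses.asdict(m) for m in results.morphometrics]
    paths["morphometrics"] = out / "morphometrics.csv"
    pd.DataFrame(morph_rows).to_csv(paths["morphometrics"], index=False)

    r2 = results.growth.r2_by_day if results.growth is not None else {}
    paths["r2_by_day"] = out / "r2_by_day.csv"
    pd.DataFrame(
        {"day": list(r2.keys()), "r2": list(r2.values())}
    ).to_csv(paths["r2_by_day"], index=False)

    import scipy
    import skimage

    from . import __version__

    manifest = {
        "config": results.config.to_dict(),
        "versions": {
            "colonytrack": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "scikit-image": skimage.__version__,
            "pandas": pd.__version__,
        },
    }
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))

    if results.config.write_overlays and results.frames is not None:
        overlay_dir = out / "overlays"
        overlay_dir.mkdir(exist_ok=True)
        for i, frame in enumerate(results.frames):
            rgb = render_overlay(
                frame, results.colonies, i, results.config.pixel_size_um
            )
            iio.imwrite(overlay_dir / f"frame_{i:04d}.png", rgb)
        paths["overlays"] = overlay_dir
    return paths
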