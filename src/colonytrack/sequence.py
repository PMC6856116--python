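"""Container for a time-lapse image sequence.

All frames are 2-D grayscale arrays sharing one shape.  Physical scale is
carried alongside the pixel data: ``pixel_size_um`` converts pixel
coordinates to micrometres and ``timestamps`` give hours since seeding for
each frame.  By convention the image origin is the top-left corner, ``x``
is the column index and ``y`` the row index (0-based); centroids are float
pixels and every micrometre value is ``px * pixel_size_um``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageSequence:
    """Ordered grayscale frames with physical metadata.

    Parameters
    ----------
    frames
        List of 2-D arrays (8- or 16-bit integer, or float), all the same
        shape, ordered by acquisition time.
    pixel_size_um
        Physical side length of one pixel in micrometres (default 4.0, a
        typical whole-well scan resolution).
    frame_interval_h
        Nominal hours between consecutive frames.
    timestamps
        Hours since seeding for each frame.  If omitted, frame ``i`` is
        stamped ``i * frame_interval_h``.
    """

    frames: list[np.ndarray]
    pixel_size_um: float = 4.0
    frame_interval_h: float = 6.0
    timestamps: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError(f"frames have mixed shapes: {sorted(shapes)}")
        for f in self.frames:
            if f.ndim != 2:
                raise ValueError("frames must be 2-D grayscale arrays")
        if not self.timestamps:
            self.timestamps = [i * self.frame_interval_h for i in range(len(self.frames))]
        if len(self.timestamps) != len(self.frames):
            raise ValueError("timestamps and frames length mismatch")
        diffs = np.diff(self.timestamps)
        if len(diffs) and not np.all(diffs > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        if not self.frames:
            raise ValueError("no frames")
        return self.frames[0].shape

    def day_reference_frame(self, day: int) -> int:
        """Index of the reference frame for culture day ``day``.

        The reference frame of day *d* is the last frame acquired at or
        before ``24 * d`` hours (frame index ``4 * d`` at the default 6-h
        interval).  All per-day quantities in the package use this rule.
        """
        if day < 1:
            raise ValueError("day must be >= 1")
        t = np.asarray(self.timestamps)
        idx = np.nonzero(t <= 24.0 * day + 1e-9)[0]
        if len(idx) == 0:
            raise ValueError(f"no frame at or before day {day}")
        return int(idx[-1])
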