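"""The TrackSet container: per-object, per-frame arena coordinates.

This is the hub type shared by the simulator, the tracker, the VTL reader /
writer and the behaviour metrics.  Coordinates are pixels of the normalised
430 px arena, origin at the upper-left corner outside the circle; missing
object-frames are NaN and carry the ``missing`` quality flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .config import ArenaConfig

# Per-object-frame quality flags.
FLAG_OK = 0
FLAG_DEVIATION = 1
FLAG_OVERLAP = 2
FLAG_MISLOCATION = 3
FLAG_MISSING = 4

FLAG_NAMES = {
    FLAG_OK: "ok",
    FLAG_DEVIATION: "deviation",
    FLAG_OVERLAP: "overlap",
    FLAG_MISLOCATION: "mislocation",
    FLAG_MISSING: "missing",
}
FLAG_CODES = {name: code for code, name in FLAG_NAMES.items()}


@dataclass
class TrackSet:
    """Per-object time series of (x, y) arena coordinates.

    Attributes
    ----------
    coords
        Array of shape ``(n_objects, n_frames, 2)``; NaN marks missing.
    fps
        Frame rate in frames per second.
    arena
        Arena geometry and photoperiod.
    flags
        ``(n_objects, n_frames)`` int8 array of quality-flag codes.
    meta
        Free-form header metadata (well id, start timestamp, ...).
    """

    coords: np.ndarray
    fps: float
    arena: ArenaConfig
    flags: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValueError("coords must have shape (n_objects, n_frames, 2)")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.flags is None:
            self.flags = np.zeros(self.coords.shape[:2], dtype=np.int8)
            self.flags[np.isnan(self.coords).any(axis=2)] = FLAG_MISSING
        else:
            self.flags = np.asarray(self.flags, dtype=np.int8)
            if self.flags.shape != self.coords.shape[:2]:
                raise ValueError("flags shape must match (n_objects, n_frames)")

    @property
    def n_objects(self) -> int:
        return self.coords.shape[0]

    @property
    def n_frames(self) -> int:
        return self.coords.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def object_track(self, i: int) -> np.ndarray:
        """(n_frames, 2) coordinate track of object ``i`` (0-based)."""
        return self.coords[i]

    def iter_objects(self) -> Iterator[np.ndarray]:
        yield from self.coords

    def inside_arena(self, margin: float = 0.0) -> bool:
        """True when every non-missing coordinate lies in the arena circle."""
        cx, cy = self.arena.center
        d = np.hypot(self.coords[..., 0] - cx, self.coords[..., 1] - cy)
        return bool(np.all((d <= self.arena.radius + margin) | np.isnan(d)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrackSet):
            return NotImplemented
        return (
            self.coords.shape == other.coords.shape
            and np.array_equal(self.coords, other.coords, equal_nan=True)
            and np.array_equal(self.flags, other.flags)
            and self.fps == other.fps
            and self.arena == other.arena
        )
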