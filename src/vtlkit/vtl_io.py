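"""Reader/writer for the VTL (video-to-location) coordinate text format.

A ``.vtl`` file replaces raw arena video with per-frame, per-object 2-D
coordinates.  Layout (normative for this package):

* header lines prefixed ``#``, as ``# key: value`` pairs; mandatory keys are
  ``format_version``, ``well_id``, ``fps``, ``diameter_px``, ``n_objects``,
  ``start_timestamp``, ``light_on`` and ``light_off``;
* then one tab-separated record per object-frame:
  ``frame  object  x  y  flag`` with frames 0-based, object ids 1-based,
  coordinates in pixels of the normalised 430 px arena printed with two
  decimal places, and ``NA`` marking missing coordinates.

Round-trips are identity at 2-decimal precision and a second
write-read-write cycle is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TextIO

import numpy as np

from .config import ArenaConfig
from .trackset import FLAG_CODES, FLAG_MISSING, FLAG_NAMES, TrackSet

FORMAT_VERSION = "1.0"

MANDATORY_KEYS = (
    "format_version",
    "well_id",
    "fps",
    "diameter_px",
    "n_objects",
    "start_timestamp",
    "light_on",
    "light_off",
)


class VtlParseError(ValueError):
    """Malformed VTL content; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


@dataclass
class VtlHeader:
    format_version: str
    well_id: str
    fps: float
    diameter_px: int
    n_objects: int
    start_timestamp: str
    light_on: float
    light_off: float
    extra: dict

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.diameter_px <= 0 or self.n_objects <= 0:
            raise VtlParseError("fps, diameter_px and n_objects must be positive")
        if self.light_on == self.light_off:
            raise VtlParseError("light_on and light_off must differ")


def write_vtl(tracks: TrackSet, destination: str | Path | TextIO) -> None:
    """Serialise a TrackSet to the VTL text format."""
    meta = tracks.meta
    header = {
        "format_version": FORMAT_VERSION,
        "well_id": str(meta.get("well_id", "well-1")),
        "fps": repr(float(tracks.fps)),
        "diameter_px": str(tracks.arena.diameter_px),
        "n_objects": str(tracks.n_objects),
        "start_timestamp": str(meta.get("start_timestamp", "lights-on")),
        "light_on": repr(float(tracks.arena.light_on)),
        "light_off": repr(float(tracks.arena.light_off)),
    }
    for key, value in sorted(meta.items()):
        if key not in ("well_id", "start_timestamp") and key not in header:
            header[key] = str(value)

    lines = [f"# {key}: {value}" for key, value in header.items()]
    for i in range(tracks.n_objects):
        for t in range(tracks.n_frames):
            x, y = tracks.coords[i, t]
            flag = FLAG_NAMES[int(tracks.flags[i, t])]
            if np.isnan(x) or np.isnan(y):
                lines.append(f"{t}\t{i + 1}\tNA\tNA\t{FLAG_NAMES[FLAG_MISSING]}")
            else:
                lines.append(f"{t}\t{i + 1}\t{x:.2f}\t{y:.2f}\t{flag}")
    text = "\n".join(lines) + "\n"
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        Path(destination).write_text(text)


def _parse_header(header_lines: list[tuple[int, str]]) -> VtlHeader:
    pairs: dict[str, str] = {}
    for lineno, line in header_lines:
        body = line.lstrip("#").strip()
        if not body:
            continue
        if ":" not in body:
            raise VtlParseError("header line lacks 'key: value'", lineno)
        key, value = body.split(":", 1)
        pairs[key.strip()] = value.strip()
    missing = [k for k in MANDATORY_KEYS if k not in pairs]
    if missing:
        raise VtlParseError(f"missing mandatory header keys: {', '.join(missing)}")
    extra = {k: v for k, v in pairs.items() if k not in MANDATORY_KEYS}
    return VtlHeader(
        format_version=pairs["format_version"],
        well_id=pairs["well_id"],
        fps=float(pairs["fps"]),
        diameter_px=int(pairs["diameter_px"]),
        n_objects=int(pairs["n_objects"]),
        start_timestamp=pairs["start_timestamp"],
        light_on=float(pairs["light_on"]),
        light_off=float(pairs["light_off"]),
        extra=extra,
    )


def read_vtl(source: str | Path | TextIO, arena: ArenaConfig | None = None) -> TrackSet:
    """Parse a VTL file back into a TrackSet.

    Unknown header keys are preserved in ``TrackSet.meta``.  Raises
    :class:`VtlParseError` (naming the line) on missing mandatory header
    keys, non-monotone frame indices, or object ids outside
    ``[1, n_objects]``.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    lines = text.splitlines()

    header_lines = []
    body_start = 0
    for idx, line in enumerate(lines):
        if line.startswith("#"):
            header_lines.append((idx + 1, line))
            body_start = idx + 1
        else:
            break
    header = _parse_header(header_lines)

    records: dict[int, list[tuple[int, float, float, int]]] = {
        i: [] for i in range(1, header.n_objects + 1)
    }
    last_frame = {i: -1 for i in records}
    for idx in range(body_start, len(lines)):
        line = lines[idx].rstrip("\n")
        if not line:
            continue
        lineno = idx + 1
        parts = line.split("\t")
        if len(parts) not in (4, 5):
            raise VtlParseError(f"expected 4 or 5 tab-separated fields, got {len(parts)}", lineno)
        try:
            frame = int(parts[0])
            obj = int(parts[1])
        except ValueError as exc:
            raise VtlParseError(f"bad frame/object index: {exc}", lineno) from None
        if not 1 <= obj <= header.n_objects:
            raise VtlParseError(
                f"object index {obj} outside [1, {header.n_objects}]", lineno
            )
        if frame <= last_frame[obj]:
            raise VtlParseError(f"non-monotone frame index {frame} for object {obj}", lineno)
        last_frame[obj] = frame
        if parts[2] == "NA" or parts[3] == "NA":
            x = y = float("nan")
        else:
            try:
                x, y = float(parts[2]), float(parts[3])
            except ValueError as exc:
                raise VtlParseError(f"bad coordinate: {exc}", lineno) from None
        flag_name = parts[4] if len(parts) == 5 else "ok"
        if flag_name not in FLAG_CODES:
            raise VtlParseError(f"unknown flag {flag_name!r}", lineno)
        records[obj].append((frame, x, y, FLAG_CODES[flag_name]))

    n_frames_set = {len(v) for v in records.values()}
    if len(n_frames_set) != 1:
        raise VtlParseError("objects have differing record counts")
    n_frames = n_frames_set.pop()
    if n_frames == 0:
        raise VtlParseError("file contains no records")

    coords = np.full((header.n_objects, n_frames, 2), np.nan)
    flags = np.zeros((header.n_objects, n_frames), dtype=np.int8)
    for obj, recs in records.items():
        for k, (frame, x, y, flag) in enumerate(recs):
            if frame != recs[0][0] + k:
                raise VtlParseError(f"frame indices of object {obj} are not contiguous")
            coords[obj - 1, k] = (x, y)
            flags[obj - 1, k] = flag

    if arena is None:
        arena = ArenaConfig(
            diameter_px=header.diameter_px,
            fps=header.fps,
            light_on=header.light_on,
            light_off=header.light_off,
            frame_size=max(ArenaConfig().frame_size, header.diameter_px),
        )
    meta = {
        "well_id": header.well_id,
        "start_timestamp": header.start_timestamp,
        **header.extra,
    }
    return TrackSet(coords=coords, fps=header.fps, arena=arena, flags=flags, meta=meta)


def vtl_stats(source: str | Path) -> dict:
    """Quick summary of a VTL file: objects, frames, duration, missing rate."""
    tracks = read_vtl(source)
    missing = int(np.isnan(tracks.coords[..., 0]).sum())
    return {
        "n_objects": tracks.n_objects,
        "n_frames": tracks.n_frames,
        "fps": tracks.fps,
        "duration_s": tracks.duration_s,
        "missing_object_frames": missing,
        "record_count": tracks.n_objects * tracks.n_frames,
    }
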