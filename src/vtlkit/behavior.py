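"""Sleep, locomotor and social-interaction metrics from coordinate tracks.

Definitions
-----------
* Rest frame: the Euclidean displacement to the next frame is strictly less
  than 3 px; the final frame inherits the preceding flag.
* Sleep episode (bout): a maximal run of rest frames lasting at least 5
  minutes, i.e. at least ``ceil(300 * fps)`` frames.
* Sleep latency: time from lights-off to the onset of the first episode
  starting at or after lights-off, censored at the dark-phase length
  (720 min) when no such episode exists.
* Locomotor activity: summed consecutive-frame displacement over the daily
  window (optionally converted to mm at 35 mm per 430 px).
* Social interaction bout: for an unordered fly pair, a maximal run of
  frames with pairwise distance <= 40 px; bouts end when the distance goes
  beyond 40 px.  Well-level values average over the pairs in the well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .config import NORMALIZED_DIAMETER_PX, WELL_DIAMETER_MM
from .trackset import FLAG_OK, TrackSet

REST_THRESHOLD_PX = 3.0
SLEEP_MIN_DURATION_S = 300.0
SOCIAL_THRESHOLD_PX = 40.0
DARK_PHASE_MIN = 720.0
PX_TO_MM = WELL_DIAMETER_MM / NORMALIZED_DIAMETER_PX


@dataclass(frozen=True)
class SleepEpisode:
    object_id: int
    start_frame: int
    end_frame: int  # half-open
    duration_s: float


@dataclass(frozen=True)
class SocialBout:
    pair: tuple[int, int]  # (i, j), i < j, 0-based object indices
    start_frame: int
    end_frame: int  # half-open
    duration_s: float


@dataclass(frozen=True)
class SleepSummary:
    daily_sleep_min: float
    bout_duration_min: float
    bout_number: int
    latency_min: float
    latency_censored: bool


def classify_rest(track: np.ndarray, rest_threshold_px: float = REST_THRESHOLD_PX) -> np.ndarray:
    """Per-frame rest flags for one object's ``(n_frames, 2)`` track.

    Frame ``t`` is rest iff the displacement from ``t`` to ``t + 1`` is
    strictly below the threshold; the final frame inherits the preceding
    flag.  NaN displacements (missing coordinates) count as rest, matching
    the physical reading of an undetectable immobile animal.
    """
    track = np.asarray(track, dtype=float)
    if track.ndim != 2 or track.shape[1] != 2:
        raise ValueError("track must have shape (n_frames, 2)")
    if track.shape[0] < 2:
        raise ValueError("rest classification needs at least 2 frames")
    step = np.hypot(*np.diff(track, axis=0).T)
    rest = ~(step >= rest_threshold_px)  # NaN -> rest
    return np.append(rest, rest[-1])


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index ranges of maximal True runs."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.diff(np.concatenate([[0], mask.view(np.int8), [0]]))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def min_sleep_frames(fps: float, min_duration_s: float = SLEEP_MIN_DURATION_S) -> int:
    """Frame count of the 5-minute rule (a run of exactly 5 min qualifies)."""
    return math.ceil(min_duration_s * fps - 1e-9)


def sleep_episodes(
    rest_flags: np.ndarray,
    fps: float,
    min_duration_s: float = SLEEP_MIN_DURATION_S,
    object_id: int = 0,
) -> list[SleepEpisode]:
    """Maximal rest runs of at least the 5-minute threshold."""
    if fps <= 0:
        raise ValueError("fps must be positive")
    min_frames = min_sleep_frames(fps, min_duration_s)
    return [
        SleepEpisode(object_id, start, end, (end - start) / fps)
        for start, end in _runs(rest_flags)
        if end - start >= min_frames
    ]


def sleep_metrics(
    episodes: list[SleepEpisode],
    fps: float,
    n_frames: int,
    window: tuple[int, int] | None = None,
    lights_off_min: float = DARK_PHASE_MIN,
) -> SleepSummary:
    """Daily sleep summary over a 24-h window aligned to lights-on.

    ``window`` is a half-open frame range spanning 24 h (defaults to the
    first 24 h of the recording); ``lights_off_min`` is the offset of
    lights-off from the window start.  Episode durations are clipped to the
    window; latency runs from lights-off to the onset of the first episode
    starting at or after it and is censored at the dark-phase length when
    no such episode exists.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    day_frames = int(round(86400.0 * fps))
    if window is None:
        window = (0, day_frames)
    start, end = window
    if end - start != day_frames:
        raise ValueError("window must span exactly 24 h of frames")
    if start < 0 or end > n_frames:
        raise ValueError("window not covered by the recording")

    clipped_frames = []
    for ep in episodes:
        ov = min(ep.end_frame, end) - max(ep.start_frame, start)
        if ov > 0:
            clipped_frames.append(ov)
    total_min = sum(clipped_frames) / fps / 60.0
    bout_number = len(clipped_frames)
    bout_duration_min = (total_min / bout_number) if bout_number else 0.0

    lights_off_frame = start + int(round(lights_off_min * 60.0 * fps))
    dark_min = (end - lights_off_frame) / fps / 60.0
    latency_min, censored = dark_min, True
    for ep in sorted(episodes, key=lambda e: e.start_frame):
        if ep.start_frame >= lights_off_frame and ep.start_frame < end:
            latency_min = (ep.start_frame - lights_off_frame) / fps / 60.0
            censored = False
            break
    return SleepSummary(total_min, bout_duration_min, bout_number, latency_min, censored)


def locomotor_distance(
    track: np.ndarray,
    window: tuple[int, int] | None = None,
    as_mm: bool = False,
) -> float:
    """Summed consecutive-frame displacement inside the window (px or mm)."""
    track = np.asarray(track, dtype=float)
    if window is not None:
        track = track[window[0] : window[1]]
    step = np.hypot(*np.diff(track, axis=0).T)
    total = float(np.nansum(step))
    return total * PX_TO_MM if as_mm else total


def social_interactions(
    tracks: TrackSet,
    interaction_threshold_px: float = SOCIAL_THRESHOLD_PX,
    window: tuple[int, int] | None = None,
    min_distance_px: float | None = None,
) -> tuple[list[SocialBout], pd.DataFrame]:
    """Pairwise social-interaction bouts and a per-pair summary.

    A bout is a maximal run of frames during which a pair's distance stays
    within ``interaction_threshold_px`` (<= 40 px by default).  Setting
    ``min_distance_px`` additionally requires the distance to be at least
    that value (off by default: very close flies still count as
    interacting).  The summary holds per-pair duration (minutes) and bout
    count over the window, plus the well-level mean over pairs.
    """
    if tracks.n_objects < 2:
        raise ValueError("social interaction needs at least 2 objects")
    start, end = window if window is not None else (0, tracks.n_frames)
    if not (0 <= start < end <= tracks.n_frames):
        raise ValueError("window not covered by the recording")

    bouts: list[SocialBout] = []
    rows = []
    for i, j in combinations(range(tracks.n_objects), 2):
        d = np.hypot(*(tracks.coords[i, start:end] - tracks.coords[j, start:end]).T)
        close = d <= interaction_threshold_px
        if min_distance_px is not None:
            close &= d >= min_distance_px
        close &= ~np.isnan(d)
        pair_bouts = [
            SocialBout((i, j), start + s, start + e, (e - s) / tracks.fps)
            for s, e in _runs(close)
        ]
        bouts.extend(pair_bouts)
        rows.append(
            {
                "object_i": i + 1,
                "object_j": j + 1,
                "social_duration_min": sum(b.duration_s for b in pair_bouts) / 60.0,
                "social_bout_number": len(pair_bouts),
            }
        )
    summary = pd.DataFrame(rows)
    return bouts, summary


def well_social_summary(pair_summary: pd.DataFrame) -> dict[str, float]:
    """Well-level social metrics: mean over the fly pairs in the well."""
    return {
        "social_duration_min": float(pair_summary["social_duration_min"].mean()),
        "social_bout_number": float(pair_summary["social_bout_number"].mean()),
    }


def performance_index(n_reference_side: int, n_stimulus_side: int) -> float:
    """T-maze choice index in [-1, 1].

    The count on the stimulus side (odorant / shock vial) is subtracted from
    the reference side (fresh air / control vial) and divided by the total;
    +1 means complete avoidance of the stimulus.
    """
    if n_reference_side < 0 or n_stimulus_side < 0:
        raise ValueError("counts must be non-negative")
    total = n_reference_side + n_stimulus_side
    if total == 0:
        raise ValueError("at least one fly must be counted")
    return (n_reference_side - n_stimulus_side) / total


@dataclass
class BehaviorSummary:
    """Per-object and per-pair daily behaviour summary for one well."""

    per_object: pd.DataFrame
    per_pair: pd.DataFrame
    well: dict = field(default_factory=dict)


def summarize_behavior(
    tracks: TrackSet,
    window: tuple[int, int] | None = None,
    rest_threshold_px: float = REST_THRESHOLD_PX,
    min_sleep_s: float = SLEEP_MIN_DURATION_S,
    interaction_threshold_px: float = SOCIAL_THRESHOLD_PX,
    lights_off_min: float = DARK_PHASE_MIN,
    mask_flagged: bool = False,
) -> BehaviorSummary:
    """Full daily behaviour summary of a TrackSet.

    With ``mask_flagged`` the object-frames carrying tracker quality flags
    are excluded: their steps contribute no distance, they are scored rest,
    and they cannot form social contacts.  By default flagged frames
    participate (a held coordinate reads as rest, which is how an
    undetected immobile fly behaves).
    """
    coords = tracks.coords
    if mask_flagged:
        coords = coords.copy()
        coords[tracks.flags != FLAG_OK] = np.nan
        tracks = TrackSet(coords, tracks.fps, tracks.arena, meta=dict(tracks.meta))

    obj_rows = []
    for i in range(tracks.n_objects):
        rest = classify_rest(coords[i], rest_threshold_px)
        eps = sleep_episodes(rest, tracks.fps, min_sleep_s, object_id=i)
        sm = sleep_metrics(eps, tracks.fps, tracks.n_frames, window, lights_off_min)
        obj_rows.append(
            {
                "object": i + 1,
                "daily_sleep_min": sm.daily_sleep_min,
                "bout_duration_min": sm.bout_duration_min,
                "bout_number": sm.bout_number,
                "latency_min": sm.latency_min,
                "latency_censored": sm.latency_censored,
                "daily_distance_px": locomotor_distance(coords[i], window),
            }
        )
    per_object = pd.DataFrame(obj_rows)

    if tracks.n_objects >= 2:
        _, per_pair = social_interactions(tracks, interaction_threshold_px, window)
        well = well_social_summary(per_pair)
    else:
        per_pair = pd.DataFrame(
            columns=["object_i", "object_j", "social_duration_min", "social_bout_number"]
        )
        well = {}
    return BehaviorSummary(per_object=per_object, per_pair=per_pair, well=well)
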