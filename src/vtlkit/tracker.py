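"""Multi-object centroid tracking of dark animals in a circular arena.

Pipeline: normalise each frame so the well maps to a 430-px circle
(`preprocess_frame`), extract connected regions darker than the local
background (`segment_objects`), optionally split merged blobs, and link
detections across frames by global minimum-cost matching
(`assign_identities`).  `evaluate_tracking` scores a TrackSet against
ground truth and attributes errors to the three observed failure modes:
deviation, overlap, and mislocation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .config import ArenaConfig, ParameterError
from .trackset import (
    FLAG_DEVIATION,
    FLAG_MISLOCATION,
    FLAG_MISSING,
    FLAG_NAMES,
    FLAG_OK,
    FLAG_OVERLAP,
    TrackSet,
)


@dataclass(frozen=True)
class Detection:
    """One dark blob reduced to an intensity-weighted centroid."""

    frame_index: int
    x: float
    y: float
    area: float
    mean_intensity: float
    shared: bool = False  # centroid obtained by splitting a merged blob


@dataclass(frozen=True)
class ArenaGeometry:
    """Location of the well circle in source-image coordinates."""

    cx: float
    cy: float
    radius: float


class WellDetectionError(RuntimeError):
    """Raised when the circular well cannot be located automatically."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class TrackerParams:
    """Tunable tracking parameters.

    Area bounds and the darkness offset follow the default rendered fly
    (30 x 14 px ellipse) and should be adjusted for other species / optics.
    """

    gate_px: float = 50.0
    min_area: float = 120.0
    max_area: float = 1500.0
    threshold_offset: float = 50.0
    edge_margin: float = 3.0
    split_merged: bool = True
    expected_area: float | None = None  # single-animal blob area, px^2


def detect_well(image: np.ndarray, radius_bounds: tuple[float, float] | None = None) -> ArenaGeometry:
    """Locate the circular well rim by a Hough circle transform on edges."""
    from skimage.feature import canny
    from skimage.transform import hough_circle, hough_circle_peaks

    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = (img - lo) / (hi - lo)
    edges = canny(img, sigma=2.0)
    size = min(image.shape)
    if radius_bounds is None:
        radius_bounds = (0.25 * size, 0.55 * size)
    radii = np.arange(int(radius_bounds[0]), int(radius_bounds[1]), 2)
    if radii.size == 0:
        raise WellDetectionError("radius search range is empty", {"bounds": radius_bounds})
    accum = hough_circle(edges, radii)
    accums, cxs, cys, rads = hough_circle_peaks(accum, radii, total_num_peaks=1)
    if len(accums) == 0 or accums[0] <= 0:
        raise WellDetectionError(
            "no circular rim found",
            {"edge_pixels": int(edges.sum()), "radii_tried": len(radii)},
        )
    return ArenaGeometry(cx=float(cxs[0]), cy=float(cys[0]), radius=float(rads[0]))


def preprocess_frame(
    image: np.ndarray,
    arena_spec: ArenaGeometry | tuple[float, float, float] | str | None = "auto",
    config: ArenaConfig | None = None,
) -> tuple[np.ndarray, ArenaGeometry]:
    """Normalise one grayscale frame to the standard 430-px arena.

    ``arena_spec`` locates the well in the source image: an explicit
    ``(cx, cy, radius)``, or ``"auto"`` for Hough-based rim detection.  The
    output frame has the configured ``frame_size``, the well centred and
    rescaled to 430 px diameter, and pixels outside the circle replaced by
    the interior median so they cannot segment.  Returns the normalised
    image and the source geometry actually used.
    """
    from skimage.transform import AffineTransform, warp

    config = config or ArenaConfig()
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.ndim != 2:
        raise ParameterError("image must be 2-D grayscale (or RGB convertible)")

    if arena_spec is None or arena_spec == "auto":
        geom = detect_well(img)
    elif isinstance(arena_spec, ArenaGeometry):
        geom = arena_spec
    else:
        geom = ArenaGeometry(*arena_spec)

    target_c = config.frame_size / 2.0
    target_r = config.diameter_px / 2.0
    same_geometry = (
        img.shape == (config.frame_size, config.frame_size)
        and abs(geom.cx - target_c) < 1e-6
        and abs(geom.cy - target_c) < 1e-6
        and abs(geom.radius - target_r) < 1e-6
    )
    if same_geometry:
        out = img.copy()
    else:
        scale = geom.radius / target_r
        tform = AffineTransform(
            scale=(scale, scale),
            translation=(geom.cx - scale * target_c, geom.cy - scale * target_c),
        )
        out = warp(
            img,
            tform,
            output_shape=(config.frame_size, config.frame_size),
            preserve_range=True,
            mode="edge",
        )

    yy, xx = np.mgrid[0 : config.frame_size, 0 : config.frame_size]
    inside = np.hypot(xx - target_c, yy - target_c) <= target_r
    interior_median = float(np.median(out[inside]))
    out[~inside] = interior_median
    return out, geom


def _weighted_centroid(ys: np.ndarray, xs: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    total = weights.sum()
    if total <= 0:
        return float(xs.mean()), float(ys.mean())
    return float((xs * weights).sum() / total), float((ys * weights).sum() / total)


def segment_objects(
    frame: np.ndarray,
    params: TrackerParams | None = None,
    config: ArenaConfig | None = None,
    frame_index: int = 0,
) -> list[Detection]:
    """Extract dark blobs from a preprocessed frame as Detections.

    A pixel belongs to a blob when it is darker than the interior median
    background by at least ``threshold_offset``; blobs are filtered by the
    area bounds and reduced to darkness-weighted centroids.  An empty list
    is a valid result.
    """
    from skimage.measure import label, regionprops

    params = params or TrackerParams()
    config = config or ArenaConfig()
    img = np.asarray(frame, dtype=float)
    target_c = config.frame_size / 2.0
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    mask = np.hypot(xx - target_c, yy - target_c) <= config.radius - params.edge_margin

    background = float(np.median(img[mask]))
    binary = mask & (img < background - params.threshold_offset)
    labels = label(binary, connectivity=2)
    detections: list[Detection] = []
    for region in regionprops(labels):
        if not params.min_area <= region.area <= params.max_area:
            continue
        ys, xs = region.coords[:, 0], region.coords[:, 1]
        weights = np.clip(background - img[ys, xs], 0.0, None)
        x, y = _weighted_centroid(ys, xs, weights)
        detections.append(
            Detection(
                frame_index=frame_index,
                x=x,
                y=y,
                area=float(region.area),
                mean_intensity=float(img[ys, xs].mean()),
            )
        )
    detections.sort(key=lambda d: (d.x, d.y))
    return detections


def _split_detection(
    det: Detection,
    frame: np.ndarray,
    params: TrackerParams,
    config: ArenaConfig,
    k: int,
    seed_points: np.ndarray | None = None,
) -> list[Detection]:
    """Split a merged blob into ``k`` centroids by seeded Lloyd iteration.

    Seeds come from ``seed_points`` (the animals' last known positions)
    when available, falling back to the extremes of the blob's principal
    axis; either way the split is deterministic.  The resulting detections
    are marked ``shared``.
    """
    img = np.asarray(frame, dtype=float)
    target_c = config.frame_size / 2.0
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    mask = np.hypot(xx - target_c, yy - target_c) <= config.radius - params.edge_margin
    background = float(np.median(img[mask]))
    binary = mask & (img < background - params.threshold_offset)

    from skimage.measure import label

    labels = label(binary, connectivity=2)
    blob_label = labels[int(round(det.y)), int(round(det.x))]
    if blob_label == 0:  # centroid off the blob (concave); use nearest labelled pixel
        ys, xs = np.nonzero(labels > 0)
        if ys.size == 0:
            return [det]
        nearest = np.argmin(np.hypot(xs - det.x, ys - det.y))
        blob_label = labels[ys[nearest], xs[nearest]]
    ys, xs = np.nonzero(labels == blob_label)
    pts = np.column_stack([xs, ys]).astype(float)
    weights = np.clip(background - img[ys, xs], 0.0, None)

    if seed_points is not None and len(seed_points) == k:
        centers = np.asarray(seed_points, dtype=float).copy()
    else:
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        proj = centered @ vt[0]
        order = np.argsort(proj)
        seeds = np.linspace(0, len(order) - 1, k).astype(int)
        centers = pts[order[seeds]]
    for _ in range(10):
        d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        assign = d2.argmin(axis=1)
        new_centers = centers.copy()
        for c in range(k):
            sel = assign == c
            if sel.any():
                w = weights[sel]
                tw = w.sum()
                if tw > 0:
                    new_centers[c] = (pts[sel] * w[:, None]).sum(axis=0) / tw
                else:
                    new_centers[c] = pts[sel].mean(axis=0)
        if np.allclose(new_centers, centers):
            break
        centers = new_centers
    out = []
    for c in range(k):
        sel = assign == c
        area = float(sel.sum())
        out.append(
            Detection(
                frame_index=det.frame_index,
                x=float(centers[c, 0]),
                y=float(centers[c, 1]),
                area=area,
                mean_intensity=float(img[ys[sel], xs[sel]].mean()) if sel.any() else det.mean_intensity,
                shared=True,
            )
        )
    out.sort(key=lambda d: (d.x, d.y))
    return out


def _maybe_split(
    detections: list[Detection],
    frame: np.ndarray,
    n_objects: int,
    params: TrackerParams,
    config: ArenaConfig,
    prev_positions: np.ndarray | None = None,
) -> list[Detection]:
    """Split oversized blobs when fewer detections than objects remain.

    ``prev_positions`` are the animals' coordinates in the previous frame;
    the positions nearest a merged blob seed its split so the pieces stay
    in correspondence with the identities that entered the merge.
    """
    if len(detections) >= n_objects or not detections:
        return detections
    expected = params.expected_area or float(np.pi * config.object_axes[0] * config.object_axes[1])
    out = list(detections)
    # Largest blobs first; split until counts match or nothing oversized remains.
    while len(out) < n_objects:
        candidates = [d for d in out if not d.shared and d.area >= 1.2 * expected]
        if not candidates:
            break
        biggest = max(candidates, key=lambda d: d.area)
        k = min(
            max(2, int(round(biggest.area / expected))),
            n_objects - len(out) + 1,
        )
        seeds = None
        if prev_positions is not None and len(prev_positions) >= k:
            dist = np.hypot(
                prev_positions[:, 0] - biggest.x, prev_positions[:, 1] - biggest.y
            )
            order = np.argsort(dist)
            # seed only from positions plausibly inside the merged blob
            if dist[order[k - 1]] <= 3.0 * np.sqrt(biggest.area):
                seeds = prev_positions[order[:k]]
        pieces = _split_detection(biggest, frame, params, config, k, seed_points=seeds)
        if len(pieces) <= 1:
            break
        out.remove(biggest)
        out.extend(pieces)
    out.sort(key=lambda d: (d.x, d.y))
    return out


def assign_identities(
    detections_by_frame: list[list[Detection]],
    n_objects: int,
    gate_px: float = 50.0,
    config: ArenaConfig | None = None,
    fps: float | None = None,
) -> TrackSet:
    """Link per-frame detections into identities by global matching.

    Every frame solves a minimum-total-distance assignment between the
    predicted positions (each object's last known coordinate) and the
    frame's detections.  Unmatched objects inherit their last coordinate
    and are flagged ``missing``; when detections are fewer than objects the
    surplus identities attach to their nearest blob and both parties are
    flagged ``overlap``; matches farther than ``gate_px`` are flagged
    ``deviation``; detections landing outside the arena circle are flagged
    ``mislocation``.  Detections within a frame are sorted canonically so
    the result is invariant to their input order.
    """
    if len(detections_by_frame) == 0:
        raise ParameterError("at least one frame of detections is required")
    if n_objects < 1:
        raise ParameterError("n_objects must be at least 1")
    config = config or ArenaConfig()
    fps = fps or config.fps
    n_frames = len(detections_by_frame)
    cx, cy = config.center

    coords = np.full((n_objects, n_frames, 2), np.nan)
    flags = np.full((n_objects, n_frames), FLAG_MISSING, dtype=np.int8)
    last = np.full((n_objects, 2), np.nan)
    # Prediction anchors: like `last`, but identities sharing a blob keep
    # their pre-merge relative offsets (translated with the blob) so they
    # can be told apart again when the blob separates.
    anchor = np.full((n_objects, 2), np.nan)
    # Constant-velocity term, reset whenever an identity is not matched
    # alone to a blob; crossing animals keep their headings, so the motion
    # model carries identity through the crossing.
    velocity = np.zeros((n_objects, 2))

    for t, dets in enumerate(detections_by_frame):
        dets = sorted(dets, key=lambda d: (d.x, d.y))
        pos = np.array([[d.x, d.y] for d in dets]) if dets else np.empty((0, 2))
        have_last = ~np.isnan(last[:, 0])

        if not dets:
            coords[:, t, :] = last
            flags[:, t] = FLAG_MISSING
            continue

        if not have_last.any():
            # Initialise identities in canonical detection order.
            for i in range(n_objects):
                j = min(i, len(dets) - 1)
                coords[i, t] = pos[j]
                flags[i, t] = FLAG_OK if i < len(dets) else FLAG_OVERLAP
                if i >= len(dets):
                    flags[min(i, len(dets) - 1), t] = FLAG_OVERLAP
            last = coords[:, t, :].copy()
            anchor = coords[:, t, :].copy()
            continue

        # Predicted position: the anchor (last distinct coordinate, carried
        # through merges) advanced by the velocity estimate; objects never
        # seen yet predict from the centre.
        predicted = anchor + velocity
        predicted[~have_last] = (cx, cy)
        cost = np.hypot(
            predicted[:, None, 0] - pos[None, :, 0],
            predicted[:, None, 1] - pos[None, :, 1],
        )
        # Likelihood-style normalisation: a long-immobile identity predicts
        # its position far more tightly than a fast mover, so its residuals
        # weigh more.  sigma grows with the current speed estimate.
        sigma = np.clip(0.5 * np.hypot(velocity[:, 0], velocity[:, 1]) + 2.0, 2.0, gate_px)
        rows, cols = linear_sum_assignment(cost / sigma[:, None])
        det_of_obj = np.full(n_objects, -1, dtype=int)
        det_of_obj[rows] = cols

        # Surplus identities attach to their nearest blob; both get overlap.
        for i in np.flatnonzero(det_of_obj < 0):
            j = int(np.argmin(cost[i]))
            det_of_obj[i] = j

        claims = np.bincount(det_of_obj, minlength=len(dets))
        for i in range(n_objects):
            j = det_of_obj[i]
            d = dets[j]
            coords[i, t] = (d.x, d.y)
            dist = cost[i, j]
            if claims[j] > 1 or d.shared:
                flags[i, t] = FLAG_OVERLAP
            elif np.hypot(d.x - cx, d.y - cy) > config.radius:
                flags[i, t] = FLAG_MISLOCATION
            elif have_last[i] and dist > gate_px:
                flags[i, t] = FLAG_DEVIATION
            else:
                flags[i, t] = FLAG_OK
        last = coords[:, t, :].copy()

        # Update anchors and velocities: identities alone on a blob follow
        # it exactly; identities sharing a blob translate as a rigid group
        # so that the group mean sits on the blob centroid.
        for j in range(len(dets)):
            members = np.flatnonzero(det_of_obj == j)
            if len(members) == 0:
                continue
            if len(members) == 1:
                i = members[0]
                if not np.isnan(anchor[i, 0]):
                    # Exponentially damped velocity: robust to single-step
                    # speed fluctuations.
                    velocity[i] = 0.5 * velocity[i] + 0.5 * (pos[j] - anchor[i])
                anchor[i] = pos[j]
            else:
                velocity[members] = 0.0
                known = members[~np.isnan(anchor[members, 0])]
                if len(known) == 0:
                    anchor[members] = pos[j]
                else:
                    anchor[members[np.isnan(anchor[members, 0])]] = pos[j]
                    shift = pos[j] - anchor[members].mean(axis=0)
                    anchor[members] += shift

    return TrackSet(coords=coords, fps=fps, arena=config, flags=flags)


def track_frames(
    frames,
    n_objects: int,
    arena_spec: ArenaGeometry | tuple[float, float, float] | str | None = "auto",
    params: TrackerParams | None = None,
    config: ArenaConfig | None = None,
    preprocessed: bool = False,
) -> TrackSet:
    """Full pipeline: preprocess, segment, split merged blobs, link.

    ``frames`` is any iterable of grayscale images.  The well is located on
    the first frame (or taken from ``arena_spec``) and the geometry reused
    for the rest of the recording.
    """
    params = params or TrackerParams()
    config = config or ArenaConfig()
    detections_by_frame: list[list[Detection]] = []
    geom: ArenaGeometry | None = None
    prev_positions: np.ndarray | None = None
    for t, frame in enumerate(frames):
        if preprocessed:
            norm = np.asarray(frame, dtype=float)
        else:
            spec = arena_spec if geom is None else geom
            norm, geom = preprocess_frame(frame, spec, config)
        dets = segment_objects(norm, params, config, frame_index=t)
        if params.split_merged:
            dets = _maybe_split(dets, norm, n_objects, params, config, prev_positions)
        if dets:
            prev_positions = np.array([[d.x, d.y] for d in dets])
        detections_by_frame.append(dets)
    return assign_identities(detections_by_frame, n_objects, params.gate_px, config)


@dataclass
class TrackingEvaluation:
    """Per-object-frame accuracy and error-type attribution."""

    accuracy: float
    n_object_frames: int
    n_correct: int
    errors: dict = field(default_factory=dict)  # {"deviation": .., "overlap": .., "mislocation": ..}
    identity_map: list | None = None


def evaluate_tracking(
    tracks: TrackSet,
    truth: TrackSet,
    tol_px: float = 10.0,
    align_identities: bool = True,
) -> TrackingEvaluation:
    """Score tracked coordinates against ground truth.

    An object-frame is correct when the tracked coordinate lies within
    ``tol_px`` of the true coordinate of the same identity (identities are
    aligned once over the whole recording by minimum mean distance, since
    tracker labels are arbitrary).  Incorrect object-frames are attributed
    to ``overlap`` (shared blob), ``mislocation`` (missing or outside the
    arena), or ``deviation`` (off-target but inside the arena).
    """
    if tracks.coords.shape != truth.coords.shape:
        raise ValueError("tracks and truth must share frame grid and object count")
    n, T = tracks.n_objects, tracks.n_frames

    if align_identities and n > 1:
        mean_d = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                d = np.hypot(*(tracks.coords[i] - truth.coords[j]).T)
                mean_d[i, j] = np.nanmean(d) if np.any(~np.isnan(d)) else np.inf
        rows, cols = linear_sum_assignment(np.nan_to_num(mean_d, posinf=1e12))
        truth_of = dict(zip(rows.tolist(), cols.tolist()))
    else:
        truth_of = {i: i for i in range(n)}

    cx, cy = tracks.arena.center
    radius = tracks.arena.radius
    n_correct = 0
    errors = {"deviation": 0, "overlap": 0, "mislocation": 0}
    for i in range(n):
        j = truth_of[i]
        d = np.hypot(*(tracks.coords[i] - truth.coords[j]).T)
        for t in range(T):
            if d[t] <= tol_px:
                n_correct += 1
                continue
            flag = int(tracks.flags[i, t])
            x, y = tracks.coords[i, t]
            if flag == FLAG_OVERLAP:
                errors["overlap"] += 1
            elif (
                flag in (FLAG_MISLOCATION, FLAG_MISSING)
                or np.isnan(d[t])
                or np.hypot(x - cx, y - cy) > radius
            ):
                errors["mislocation"] += 1
            else:
                errors["deviation"] += 1
    total = n * T
    return TrackingEvaluation(
        accuracy=n_correct / total,
        n_object_frames=total,
        n_correct=n_correct,
        errors=errors,
        identity_map=[(i + 1, truth_of[i] + 1) for i in range(n)],
    )
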