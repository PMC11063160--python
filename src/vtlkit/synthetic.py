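"""Synthetic data generators: arena trajectories, rendered frames, screen
phenotype tables, and LLM-style response texts.

The trajectory model is a two-state (active/rest) semi-Markov walk inside a
circular well.  It is deliberately the *simplest* generative model whose
output satisfies the behavioural definitions downstream: rest-state frames
move strictly less than the 3 px immobility threshold, active steps always
exceed it, dwell times are exponential, and the dark phase lengthens rest
dwells so that night sleep consolidates.  Ground-truth state labels are
emitted alongside the coordinates so every metric can be checked against a
direct scan of the generating states.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ArenaConfig, BehaviorParams, ParameterError
from .trackset import TrackSet
from . import lexicon

STATE_ACTIVE = 0
STATE_REST = 1

_REFLECT_MAX_ITER = 8
_HEADING_REDRAW_MAX = 25


def _is_dark(t_s: float, config: ArenaConfig) -> bool:
    """Dark-phase predicate for elapsed seconds since lights-on."""
    hour = (config.light_on + t_s / 3600.0) % 24.0
    on, off = config.light_on, config.light_off
    if on < off:
        return not (on <= hour < off)
    return off <= hour < on


def _sample_states(
    rng: np.random.Generator,
    n_frames: int,
    params: BehaviorParams,
    config: ArenaConfig,
) -> np.ndarray:
    """Per-frame state labels from alternating exponential dwells."""
    states = np.empty(n_frames, dtype=np.int8)
    if params.mean_rest_bout_s == 0:
        states[:] = STATE_ACTIVE
        return states
    if params.mean_active_bout_s == 0:
        states[:] = STATE_REST
        return states
    p_rest = params.mean_rest_bout_s / (params.mean_rest_bout_s + params.mean_active_bout_s)
    state = STATE_REST if rng.random() < p_rest else STATE_ACTIVE
    t = 0
    while t < n_frames:
        if state == STATE_REST:
            mean = params.mean_rest_bout_s
            if _is_dark(t / config.fps, config):
                mean *= params.dark_rest_multiplier
        else:
            mean = params.mean_active_bout_s
        dwell_frames = max(1, int(round(rng.exponential(mean) * config.fps)))
        states[t : t + dwell_frames] = state
        t += dwell_frames
        state = STATE_REST if state == STATE_ACTIVE else STATE_ACTIVE
    return states


def _reflect_segment(p: np.ndarray, q: np.ndarray, center: np.ndarray, rmax: float) -> np.ndarray:
    """Specular reflection of the segment p->q off the circle of radius rmax."""
    p = p.astype(float).copy()
    q = q.astype(float).copy()
    for _ in range(_REFLECT_MAX_ITER):
        if np.hypot(*(q - center)) <= rmax:
            return q
        d = q - p
        f = p - center
        a = float(d @ d)
        b = 2.0 * float(f @ d)
        c = float(f @ f) - rmax * rmax
        disc = b * b - 4.0 * a * c
        if a == 0.0 or disc < 0.0:
            break
        s = (-b + np.sqrt(disc)) / (2.0 * a)
        s = min(max(s, 0.0), 1.0)
        hit = p + s * d
        nhat = (hit - center) / rmax
        v = q - hit
        v = v - 2.0 * float(v @ nhat) * nhat
        p, q = hit, hit + v
    # Numerical fallback: fold radially just inside the boundary.
    dq = q - center
    norm = np.hypot(*dq)
    if norm > rmax:
        q = center + dq * (rmax * 0.999 / norm)
    return q


def simulate_trajectories(
    config: ArenaConfig,
    params: BehaviorParams,
    n_objects: int,
    duration_s: float,
) -> tuple[TrackSet, np.ndarray]:
    """Simulate ``n_objects`` two-state trajectories in one well.

    Returns
    -------
    tracks : TrackSet
        Coordinates of every object at every frame, all inside the arena.
    states : ndarray of shape (n_objects, n_frames)
        Ground-truth labels, ``STATE_ACTIVE`` (0) or ``STATE_REST`` (1).
        The label of frame ``t`` is the state that generated the step from
        frame ``t`` to ``t + 1``; the final frame repeats the preceding
        label, mirroring how the rest classifier handles the last frame.

    Notes
    -----
    The recording is taken to start at lights-on.  Steps that would leave the
    arena are reflected specularly at the wall; if a reflected *active* step
    would net less than the 3 px rest threshold, the heading is redrawn so
    active frames are never mis-scored as rest.
    """
    if n_objects < 1:
        raise ParameterError("n_objects must be at least 1")
    if duration_s <= 0:
        raise ParameterError("duration_s must be positive")
    n_frames = max(2, int(round(duration_s * config.fps)))
    rng = np.random.default_rng(params.seed)
    center = np.asarray(config.center)
    rmax = config.radius - max(config.object_axes)  # whole body stays inside
    thresh = params.rest_threshold_px

    states = np.stack(
        [_sample_states(rng, n_frames, params, config) for _ in range(n_objects)]
    )

    coords = np.empty((n_objects, n_frames, 2), dtype=float)
    min_sep = params.min_separation_px

    def _sep_ok(i: int, cand: np.ndarray, current: np.ndarray, others: np.ndarray) -> bool:
        """Rigid bodies: a step may not close below the contact distance
        (but may stay as close as it already is)."""
        if others.shape[0] == 0:
            return True
        new_min = float(np.min(np.hypot(*(others - cand).T)))
        if new_min >= min_sep:
            return True
        cur_min = float(np.min(np.hypot(*(others - current).T)))
        return new_min >= cur_min

    # Start positions: uniform in the disc, rejected below contact distance.
    for i in range(n_objects):
        for _ in range(200):
            r0 = rmax * np.sqrt(rng.random())
            a0 = rng.uniform(0.0, 2.0 * np.pi)
            p0 = center + [r0 * np.cos(a0), r0 * np.sin(a0)]
            if i == 0 or np.min(np.hypot(*(coords[:i, 0] - p0).T)) >= min_sep:
                break
        coords[i, 0] = p0

    heading = rng.uniform(0.0, 2.0 * np.pi, n_objects)
    # Walking speed is a per-bout trait with small frame-to-frame jitter:
    # within one active bout an animal keeps a characteristic pace.
    bout_speed = np.full(n_objects, params.active_step_mean_px)

    for t in range(n_frames - 1):
        pos_t = coords[:, t, :]
        for i in range(n_objects):
            p = pos_t[i]
            # Neighbour positions: already-updated ones at t + 1, rest at t.
            others = np.array(
                [coords[j, t + 1] if j < i else pos_t[j] for j in range(n_objects) if j != i]
            ).reshape(-1, 2)
            if states[i, t] == STATE_REST:
                q = None
                for _ in range(5):
                    r = rng.random() * params.rest_jitter_px
                    theta = rng.uniform(0.0, 2.0 * np.pi)
                    cand = _reflect_segment(p, p + [r * np.cos(theta), r * np.sin(theta)], center, rmax)
                    if _sep_ok(i, cand, p, others):
                        q = cand
                        break
                if q is None:
                    q = p.copy()  # stay put: trivially a rest frame
            else:
                if t == 0 or states[i, t - 1] != STATE_ACTIVE:
                    bout_speed[i] = thresh + rng.exponential(
                        params.active_step_mean_px - thresh
                    )
                    heading[i] = rng.uniform(0.0, 2.0 * np.pi)
                r = thresh + (bout_speed[i] - thresh) * rng.uniform(0.7, 1.3)
                r = min(r, rmax)
                if n_objects > 1 and rng.random() < params.social_attraction:
                    j = int(np.argmin(np.hypot(*(others - p).T)))
                    delta = others[j] - p
                    theta = float(np.arctan2(delta[1], delta[0]))
                else:
                    # Correlated walk: runs with gradual turns.
                    theta = heading[i] + rng.normal(0.0, params.heading_turn_sd)
                q = None
                fallback = None
                for _ in range(_HEADING_REDRAW_MAX):
                    cand = p + [r * np.cos(theta), r * np.sin(theta)]
                    cand = _reflect_segment(p, cand, center, rmax)
                    if np.hypot(*(cand - p)) >= thresh:
                        if _sep_ok(i, cand, p, others):
                            q = cand
                            break
                        if fallback is None:
                            fallback = cand
                    theta = rng.uniform(0.0, 2.0 * np.pi)
                if q is None and fallback is not None:
                    q = fallback  # crowded corner: physicality yields to the
                    # active-displacement guarantee
                if q is None:  # step straight toward the centre, always valid
                    delta = center - p
                    theta = float(np.arctan2(delta[1], delta[0]))
                    q = p + [r * np.cos(theta), r * np.sin(theta)]
                delta = q - p
                heading[i] = float(np.arctan2(delta[1], delta[0]))
            coords[i, t + 1, :] = q

    states[:, -1] = states[:, -2]
    tracks = TrackSet(
        coords=coords,
        fps=config.fps,
        arena=config,
        meta={"well_id": "synthetic", "start_timestamp": "lights-on", "seed": params.seed},
    )
    return tracks, states


def _headings(coords: np.ndarray) -> np.ndarray:
    """Per-frame body orientation from the outgoing displacement."""
    d = np.diff(coords, axis=1)
    ang = np.arctan2(d[..., 1], d[..., 0])
    ang = np.concatenate([ang, ang[:, -1:]], axis=1)
    # Hold orientation through (near-)stationary frames.
    still = np.hypot(d[..., 0], d[..., 1]) < 0.5
    for i in range(ang.shape[0]):
        for t in range(1, ang.shape[1] - 1):
            if still[i, t]:
                ang[i, t] = ang[i, t - 1]
    return ang


def render_frame(
    positions: np.ndarray,
    config: ArenaConfig,
    orientations: np.ndarray | None = None,
    noise_rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one 8-bit grayscale frame: lit well, dark rim, dark ellipses."""
    from skimage.draw import ellipse as draw_ellipse

    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    size = config.frame_size
    if positions.size and (
        positions.min() < 0 or positions.max() >= size
    ):
        raise ParameterError("object coordinates fall outside the frame bounds")
    cx, cy = config.center
    yy, xx = np.mgrid[0:size, 0:size]
    dist = np.hypot(xx - cx, yy - cy)

    img = np.full((size, size), float(config.background_level))
    img[dist > config.radius] = max(config.background_level - 30, 0)
    rim = (dist >= config.radius - 2.0) & (dist <= config.radius + 2.0)
    img[rim] = config.object_level

    ax_major, ax_minor = config.object_axes
    for k, (x, y) in enumerate(positions):
        rot = 0.0 if orientations is None else float(orientations[k])
        rr, cc = draw_ellipse(y, x, ax_minor, ax_major, shape=img.shape, rotation=rot)
        img[rr, cc] = config.object_level

    if noise_rng is not None and config.noise_sd > 0:
        img = img + noise_rng.normal(0.0, config.noise_sd, img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def render_frames(
    tracks: TrackSet,
    config: ArenaConfig | None = None,
    noise_seed: int = 0,
) -> np.ndarray:
    """Render a TrackSet as a stack of grayscale frames.

    Deterministic for a given ``noise_seed``.  Returns an array of shape
    ``(n_frames, frame_size, frame_size)`` with dtype uint8.
    """
    config = config or tracks.arena
    if not tracks.inside_arena():
        raise ParameterError("all coordinates must lie inside the arena circle")
    rng = np.random.default_rng(noise_seed)
    orient = _headings(tracks.coords)
    frames = [
        render_frame(tracks.coords[:, t, :], config, orient[:, t], rng)
        for t in range(tracks.n_frames)
    ]
    return np.stack(frames)


def write_frames(frames, directory: str | Path, prefix: str = "frame") -> list[Path]:
    """Write a frame stack as zero-padded PNG files."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for t, frame in enumerate(frames):
        path = directory / f"{prefix}_{t:06d}.png"
        iio.imwrite(path, frame)
        paths.append(path)
    return paths


def write_ground_truth(
    tracks: TrackSet,
    states: np.ndarray,
    destination: str | Path,
    config: ArenaConfig | None = None,
    params: BehaviorParams | None = None,
) -> Path:
    """Write ground-truth coordinates/states as TSV with a JSON sidecar."""
    destination = Path(destination)
    rows = []
    for i in range(tracks.n_objects):
        for t in range(tracks.n_frames):
            rows.append(
                (
                    t,
                    i + 1,
                    round(float(tracks.coords[i, t, 0]), 2),
                    round(float(tracks.coords[i, t, 1]), 2),
                    "rest" if states[i, t] == STATE_REST else "active",
                )
            )
    df = pd.DataFrame(rows, columns=["frame", "object", "x", "y", "state"])
    df.to_csv(destination, sep="\t", index=False)
    sidecar = {
        "fps": tracks.fps,
        "n_objects": tracks.n_objects,
        "arena": {"diameter_px": tracks.arena.diameter_px, "frame_size": tracks.arena.frame_size},
    }
    if params is not None:
        sidecar["params"] = {
            k: getattr(params, k)
            for k in (
                "mean_active_bout_s",
                "mean_rest_bout_s",
                "active_step_mean_px",
                "rest_jitter_px",
                "social_attraction",
                "dark_rest_multiplier",
                "seed",
            )
        }
    destination.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return destination


# ---------------------------------------------------------------------------
# Screen phenotype tables
# ---------------------------------------------------------------------------

def simulate_screen(
    n_lines: int,
    base_mean: float = 600.0,
    base_sd: float = 120.0,
    planted_hits: list[tuple[int, float]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-line phenotype table with optional planted outlier lines.

    Non-planted lines are drawn from Normal(base_mean, base_sd); a planted
    ``(index, shift_in_sd)`` entry offsets that line by ``shift_in_sd *
    base_sd``.  Defaults emulate a daily-sleep screen (minutes per day).
    """
    if n_lines < 3:
        raise ParameterError("n_lines must be at least 3")
    if base_sd < 0:
        raise ParameterError("base_sd must be non-negative")
    planted_hits = planted_hits or []
    indices = [i for i, _ in planted_hits]
    if len(set(indices)) != len(indices):
        raise ParameterError("duplicate planted indices")
    for i in indices:
        if not 0 <= i < n_lines:
            raise ParameterError(f"planted index {i} outside [0, {n_lines})")
    rng = np.random.default_rng(seed)
    values = rng.normal(base_mean, base_sd, n_lines)
    for i, shift in planted_hits:
        values[i] = base_mean + shift * base_sd
    return pd.DataFrame(
        {
            "line_id": [f"line_{i:05d}" for i in range(n_lines)],
            "gene_symbol": [f"gene{i:05d}" for i in range(n_lines)],
            "value": values,
        }
    )


# ---------------------------------------------------------------------------
# LLM-style response texts
# ---------------------------------------------------------------------------

_POSITIVE_INTERPRETATION_TEMPLATES = [
    "Yes, the protein {g} is involved in regulating {b} in fruit flies. "
    "Mutations in the gene encoding {g} have been shown to alter {b} patterns.",
    "The protein {g} plays a role in {b} regulation. Studies using RNA "
    "interference against {g} report clear changes in {b} of fruit flies.",
    "{g} is a regulator of {b}. Overexpression of {g} in neurons modifies {b} "
    "and related circadian behaviors in Drosophila.",
]

_NEGATIVE_INTERPRETATION_TEMPLATE = (
    "As of my knowledge cutoff, I {phrase} information linking the protein "
    "{g} to the regulation of {b} in fruit flies."
)

_POSITIVE_REASONING_TEMPLATES = [
    "Based on their shared pathways, it {phrase} that {a} modulates {b} "
    "through downstream signaling.",
    "Given that {a} and {b} both act in the fly brain, it {phrase} that {a} "
    "influences the activity of {b}.",
]

_NEGATIVE_REASONING_TEMPLATES = [
    # Contains the standalone negative keyword "no".
    "There is no established relationship between {a} and {b}; it can be "
    "hypothesized that they act in independent pathways.",
    # Omits every reasoning key phrase.
    "The genes {a} and {b} act in unrelated processes and a direct mechanistic "
    "link between them has never been demonstrated experimentally.",
]


def simulate_responses(
    n: int,
    positive_rate: float,
    mode: str = "interpretation",
    seed: int = 0,
    behavior: str = "sleep",
) -> pd.DataFrame:
    """Response-text table with ground-truth labels.

    In ``interpretation`` mode, negative texts embed one of the 27 negative
    key phrases; positive texts avoid them all.  In ``reasoning`` mode,
    positive texts contain a reasoning key phrase and never the standalone
    word "no"; negative texts either carry "no" or omit every reasoning
    phrase.
    """
    if not 0.0 <= positive_rate <= 1.0:
        raise ParameterError("positive_rate must lie in [0, 1]")
    if mode not in ("interpretation", "reasoning"):
        raise ParameterError("mode must be 'interpretation' or 'reasoning'")
    if n < 0:
        raise ParameterError("n must be non-negative")
    rng = np.random.default_rng(seed)
    labels = rng.random(n) < positive_rate
    rows = []
    for k in range(n):
        gene_a = f"GENE{k:05d}"
        gene_b = f"GENE{k:05d}B"
        if mode == "interpretation":
            if labels[k]:
                tpl = _POSITIVE_INTERPRETATION_TEMPLATES[
                    rng.integers(len(_POSITIVE_INTERPRETATION_TEMPLATES))
                ]
                text = tpl.format(g=gene_a, b=behavior)
            else:
                phrase = lexicon.INTERPRETATION_NEGATIVE_PHRASES[
                    rng.integers(len(lexicon.INTERPRETATION_NEGATIVE_PHRASES))
                ]
                text = _NEGATIVE_INTERPRETATION_TEMPLATE.format(
                    phrase=phrase, g=gene_a, b=behavior
                )
        else:
            if labels[k]:
                tpl = _POSITIVE_REASONING_TEMPLATES[
                    rng.integers(len(_POSITIVE_REASONING_TEMPLATES))
                ]
                phrase = lexicon.REASONING_POSITIVE_PHRASES[
                    rng.integers(len(lexicon.REASONING_POSITIVE_PHRASES))
                ]
                text = tpl.format(phrase=phrase, a=gene_a, b=gene_b)
            else:
                tpl = _NEGATIVE_REASONING_TEMPLATES[
                    rng.integers(len(_NEGATIVE_REASONING_TEMPLATES))
                ]
                text = tpl.format(a=gene_a, b=gene_b)
        rows.append((k, behavior, text, bool(labels[k])))
    return pd.DataFrame(rows, columns=["id", "behavior", "response_text", "label"])
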