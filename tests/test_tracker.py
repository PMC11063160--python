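"""Tracker: preprocessing, segmentation, assignment and evaluation."""

from itertools import permutations

import numpy as np
import pytest

from vtlkit import ArenaConfig, BehaviorParams, ParameterError, TrackSet
from vtlkit.synthetic import render_frame, render_frames, simulate_trajectories
from vtlkit.tracker import (
    ArenaGeometry,
    Detection,
    TrackerParams,
    assign_identities,
    evaluate_tracking,
    preprocess_frame,
    segment_objects,
    track_frames,
)
from vtlkit.trackset import FLAG_DEVIATION, FLAG_MISSING, FLAG_OK, FLAG_OVERLAP


def _det(t, x, y, area=330.0):
    return Detection(frame_index=t, x=x, y=y, area=area, mean_intensity=60.0)


class TestPreprocess:
    def test_identity_when_already_normalized(self):
        cfg = ArenaConfig(noise_sd=0.0)
        cx, cy = cfg.center
        img = render_frame(np.array([[cx + 50, cy - 30]]), cfg)
        geom = ArenaGeometry(cx, cy, cfg.radius)
        out, used = preprocess_frame(img, geom, cfg)
        yy, xx = np.mgrid[0 : cfg.frame_size, 0 : cfg.frame_size]
        inside = np.hypot(xx - cx, yy - cy) <= cfg.radius - 1
        assert np.array_equal(out[inside], img.astype(float)[inside])

    def test_half_size_well_is_upscaled_to_430(self):
        small = ArenaConfig(diameter_px=214, frame_size=236, noise_sd=0.0, object_axes=(8, 4))
        cx, cy = small.center
        img = render_frame(np.array([[cx, cy]]), small)
        out, _ = preprocess_frame(img, ArenaGeometry(cx, cy, small.radius + 0.5), ArenaConfig())
        cfg = ArenaConfig()
        # the dark rim of the source well must now sit at radius ~215
        tc = cfg.frame_size / 2.0
        yy, xx = np.mgrid[0 : cfg.frame_size, 0 : cfg.frame_size]
        r = np.hypot(xx - tc, yy - tc)
        ring = (r > cfg.radius - 6) & (r < cfg.radius - 2)
        assert out[ring].mean() < 150  # rim darkness mapped to the 430-px circle

    def test_auto_detection_on_offset_well(self):
        src = ArenaConfig(diameter_px=300, frame_size=420, noise_sd=1.0)
        cx, cy = src.center
        img = render_frame(np.empty((0, 2)), src, noise_rng=np.random.default_rng(0))
        # shift the well off-centre by cropping asymmetrically
        shifted = np.roll(img, (15, -22), axis=(0, 1))
        out, geom = preprocess_frame(shifted, "auto", ArenaConfig())
        assert abs(geom.radius - src.radius) <= 4
        assert abs(geom.cy - (cy + 15)) <= 4 and abs(geom.cx - (cx - 22)) <= 4
        # masked (outside-circle) area complements pi * 215^2 within 1 %
        cfg = ArenaConfig()
        tc = cfg.frame_size / 2.0
        yy, xx = np.mgrid[0 : cfg.frame_size, 0 : cfg.frame_size]
        inside = np.hypot(xx - tc, yy - tc) <= cfg.radius
        assert inside.sum() == pytest.approx(np.pi * 215.0**2, rel=0.01)


class TestSegmentation:
    def test_noise_only_frame_yields_no_detections(self):
        cfg = ArenaConfig(noise_sd=3.0)
        img = render_frame(np.empty((0, 2)), cfg, noise_rng=np.random.default_rng(4))
        norm, _ = preprocess_frame(img, ArenaGeometry(*cfg.center, cfg.radius), cfg)
        assert segment_objects(norm, TrackerParams(), cfg) == []

    def test_single_ellipse_centroid_within_one_pixel(self):
        cfg = ArenaConfig(noise_sd=0.0)
        img = render_frame(np.array([[100.0, 120.0]]), cfg)
        dets = segment_objects(img.astype(float), TrackerParams(), cfg)
        assert len(dets) == 1
        assert abs(dets[0].x - 100.0) <= 1.0 and abs(dets[0].y - 120.0) <= 1.0

    def test_merged_pair_area_is_roughly_additive(self):
        cfg = ArenaConfig(noise_sd=0.0)
        img_single = render_frame(np.array([[200.0, 200.0]]), cfg)
        single_area = segment_objects(img_single.astype(float), TrackerParams(), cfg)[0].area
        img = render_frame(np.array([[200.0, 200.0], [214.0, 204.0]]), cfg)
        dets = segment_objects(img.astype(float), TrackerParams(), cfg)
        assert len(dets) == 1
        assert dets[0].area == pytest.approx(2 * single_area, rel=0.25)


class TestAssignment:
    def test_two_far_objects_keep_identities(self):
        frames = [
            [_det(t, 100.0 + t, 100.0), _det(t, 300.0, 300.0 - t)] for t in range(20)
        ]
        ts = assign_identities(frames, 2)
        assert np.allclose(ts.coords[0, :, 0], 100.0 + np.arange(20))
        assert np.allclose(ts.coords[1, :, 1], 300.0 - np.arange(20))
        assert (ts.flags == FLAG_OK).all()

    @pytest.mark.parametrize("case_seed", range(50))
    def test_matches_brute_force_permutation_minimum(self, case_seed):
        """One-step assignment equals the exhaustive-permutation optimum."""
        rng = np.random.default_rng(case_seed)
        n = int(rng.integers(2, 7))
        cfg = ArenaConfig()
        cx, cy = cfg.center
        start = np.column_stack(
            [rng.uniform(cx - 150, cx + 150, n), rng.uniform(cy - 150, cy + 150, n)]
        )
        dets1 = start + rng.uniform(-20, 20, (n, 2))
        frames = [
            [_det(0, x, y) for x, y in start],
            [_det(1, x, y) for x, y in dets1],
        ]
        ts = assign_identities(frames, n, gate_px=1e9, config=cfg)
        got_cost = sum(
            np.hypot(*(ts.coords[i, 1] - ts.coords[i, 0])) for i in range(n)
        )
        best = min(
            sum(np.hypot(*(dets1[list(perm)][i] - start[i])) for i in range(n))
            for perm in permutations(range(n))
        )
        assert got_cost == pytest.approx(best, abs=1e-9)

    def test_permutation_invariance_of_detection_order(self, rng):
        n = 4
        base = [
            [_det(t, 100.0 + 40 * i + t, 100.0 + 30 * i) for i in range(n)]
            for t in range(10)
        ]
        shuffled = [list(rng.permutation(len(f))) for f in base]
        frames_shuffled = [[f[j] for j in order] for f, order in zip(base, shuffled)]
        a = assign_identities(base, n)
        b = assign_identities(frames_shuffled, n)
        assert a == b

    def test_missing_detection_marks_overlap_pair(self):
        """5 objects, one frame with 4 blobs: the two merged identities share
        coordinates and both carry the overlap flag."""
        pos0 = [(100.0, 100.0), (200.0, 100.0), (300.0, 100.0), (100.0, 300.0), (200.0, 300.0)]
        frames = [
            [_det(0, x, y) for x, y in pos0],
            [_det(1, x, y) for x, y in pos0[:4]],  # objects 4 and 5 merged
        ]
        ts = assign_identities(frames, 5)
        overlap = np.flatnonzero(ts.flags[:, 1] == FLAG_OVERLAP)
        assert len(overlap) == 2
        i, j = overlap
        assert np.array_equal(ts.coords[i, 1], ts.coords[j, 1])

    def test_zero_frames_rejected(self):
        with pytest.raises(ParameterError):
            assign_identities([], 2)

    def test_no_teleportation_without_flag(self, arena):
        """Any displacement beyond the gate co-occurs with a non-ok flag."""
        tracks, _ = simulate_trajectories(arena, BehaviorParams(seed=13), 4, 30.0)
        frames = render_frames(tracks, noise_seed=13)
        geom = ArenaGeometry(*arena.center, arena.radius)
        params = TrackerParams()
        ts = track_frames(frames, 4, geom, params, arena)
        step = np.hypot(*np.diff(ts.coords, axis=1).transpose(2, 0, 1))
        jumps = step > params.gate_px
        if jumps.any():
            objs, ts_idx = np.nonzero(jumps)
            for i, t in zip(objs, ts_idx):
                assert (ts.flags[i, t] != FLAG_OK) or (ts.flags[i, t + 1] != FLAG_OK)


class TestEvaluation:
    def _truth(self, arena):
        tracks, _ = simulate_trajectories(arena, BehaviorParams(seed=21), 3, 20.0)
        return tracks

    def test_identical_tracks_score_one(self, arena):
        truth = self._truth(arena)
        ev = evaluate_tracking(truth, truth, tol_px=10.0)
        assert ev.accuracy == 1.0
        assert sum(ev.errors.values()) == 0

    def test_single_displaced_frame_counts_once(self, arena):
        truth = self._truth(arena)
        tracked = TrackSet(truth.coords.copy(), truth.fps, truth.arena)
        tracked.coords[1, 5] += (40.0, 0.0)
        ev = evaluate_tracking(tracked, truth, tol_px=10.0, align_identities=False)
        total = truth.n_objects * truth.n_frames
        assert ev.accuracy == pytest.approx(1.0 - 1.0 / total)
        assert ev.errors["deviation"] == 1

    def test_dimension_mismatch_rejected(self, arena):
        truth = self._truth(arena)
        other = TrackSet(truth.coords[:, :-1].copy(), truth.fps, truth.arena)
        with pytest.raises(ValueError):
            evaluate_tracking(other, truth)


class TestDegradation:
    def test_accuracy_non_increasing_in_density_and_noise(self):
        """Crowding and sensor noise can only hurt the tracker."""
        base = ArenaConfig()
        geom = ArenaGeometry(*base.center, base.radius)

        def acc(n, noise_sd, seed=31):
            cfg = ArenaConfig(noise_sd=noise_sd)
            tracks, _ = simulate_trajectories(cfg, BehaviorParams(seed=seed), n, 25.0)
            frames = render_frames(tracks, noise_seed=seed)
            ts = track_frames(frames, n, geom, TrackerParams(), cfg)
            return evaluate_tracking(ts, tracks, tol_px=10.0).accuracy

    # density 1 vs 5 and clean vs very noisy; small tolerance for sampling noise
        assert acc(1, 3.0) + 1e-9 >= acc(5, 3.0) - 0.02
        assert acc(2, 0.0) + 1e-9 >= acc(2, 25.0) - 0.02
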