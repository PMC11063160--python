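"""Behaviour metrics: the 3 px / 5 min / 40 px rules and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vtlkit import ArenaConfig, BehaviorParams, TrackSet
from vtlkit.behavior import (
    classify_rest,
    locomotor_distance,
    min_sleep_frames,
    performance_index,
    sleep_episodes,
    sleep_metrics,
    social_interactions,
    summarize_behavior,
    well_social_summary,
)
from vtlkit.synthetic import STATE_REST, simulate_trajectories

ARENA = ArenaConfig()


def _track_from_steps(steps):
    """1-D walk along x with the given per-frame displacements."""
    x = np.concatenate([[100.0], 100.0 + np.cumsum(steps)])
    return np.column_stack([x, np.full_like(x, 100.0)])


class TestRestRule:
    def test_displacement_just_below_threshold_is_rest(self):
        track = _track_from_steps([2.9])
        assert classify_rest(track).tolist() == [True, True]

    def test_displacement_at_threshold_is_not_rest(self):
        track = _track_from_steps([3.0])
        assert classify_rest(track).tolist() == [False, False]

    def test_stationary_track_all_rest(self):
        track = np.full((50, 2), 123.0)
        assert classify_rest(track).all()

    def test_final_frame_inherits_previous_flag(self):
        track = _track_from_steps([5.0, 0.1])
        flags = classify_rest(track)
        assert flags.tolist() == [False, True, True]

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            classify_rest(np.array([[1.0, 2.0]]))


class TestSleepEpisodes:
    def _flags(self, runs):
        """Alternating rest/active runs, starting with rest."""
        out = []
        rest = True
        for n in runs:
            out.extend([rest] * n)
            rest = not rest
        return np.array(out)

    def test_exact_five_minutes_qualifies(self):
        assert min_sleep_frames(7.2) == 2160
        flags = self._flags([2160, 10])
        eps = sleep_episodes(flags, fps=7.2)
        assert len(eps) == 1
        assert eps[0].duration_s == pytest.approx(300.0)

    def test_one_frame_short_does_not_qualify(self):
        flags = self._flags([2159, 10])
        assert sleep_episodes(flags, fps=7.2) == []

    def test_run_length_scan_example(self):
        flags = self._flags([3000, 500, 1000, 500, 2500])
        eps = sleep_episodes(flags, fps=7.2)
        assert [e.end_frame - e.start_frame for e in eps] == [3000, 2500]
        assert eps[0].duration_s == pytest.approx(3000 / 7.2)
        assert eps[1].duration_s == pytest.approx(2500 / 7.2)


class TestSleepMetrics:
    FPS = 1.0
    DAY = 86400

    def test_episode_spanning_dark_phase(self):
        from vtlkit.behavior import SleepEpisode

        dark_start = 720 * 60  # frames at 1 fps
        eps = [SleepEpisode(0, dark_start, self.DAY, 720 * 60.0)]
        sm = sleep_metrics(eps, self.FPS, self.DAY)
        assert sm.daily_sleep_min == pytest.approx(720.0)
        assert sm.bout_number == 1
        assert sm.latency_min == pytest.approx(0.0)
        assert not sm.latency_censored

    def test_no_episodes_censors_latency(self):
        sm = sleep_metrics([], self.FPS, self.DAY)
        assert sm.daily_sleep_min == 0.0
        assert sm.bout_number == 0
        assert sm.latency_min == pytest.approx(720.0)
        assert sm.latency_censored

    def test_sleep_wake_conservation(self):
        from vtlkit.behavior import SleepEpisode

        eps = [
            SleepEpisode(0, 1000, 1000 + 400 * 60, 400 * 60.0),
            SleepEpisode(0, 50000, 50000 + 350 * 60, 350 * 60.0),
        ]
        sm = sleep_metrics(eps, self.FPS, self.DAY)
        wake = 1440.0 - sm.daily_sleep_min
        assert sm.daily_sleep_min + wake == pytest.approx(1440.0)
        assert sm.daily_sleep_min <= 1440.0

    def test_uncovered_window_rejected(self):
        with pytest.raises(ValueError):
            sleep_metrics([], self.FPS, self.DAY - 1)


class TestLocomotor:
    def test_stationary_is_zero(self):
        assert locomotor_distance(np.full((30, 2), 5.0)) == 0.0

    def test_three_four_five_triangle(self):
        track = np.array([[0.0, 0.0], [3.0, 4.0], [3.0, 4.0]])
        assert locomotor_distance(track) == pytest.approx(5.0)

    def test_mm_conversion(self):
        track = np.array([[0.0, 0.0], [430.0, 0.0]])
        assert locomotor_distance(track, as_mm=True) == pytest.approx(35.0)

    def test_matches_direct_step_sum_on_simulation(self, short_sim):
        tracks, _, _ = short_sim
        for i in range(tracks.n_objects):
            direct = float(
                np.hypot(*np.diff(tracks.coords[i], axis=0).T).sum()
            )
            assert locomotor_distance(tracks.coords[i]) == pytest.approx(direct)


class TestSocial:
    def _pair_tracks(self, distances):
        """Two objects on the x-axis separated by the given per-frame distances."""
        n = len(distances)
        a = np.column_stack([np.full(n, 100.0), np.full(n, 100.0)])
        b = np.column_stack([100.0 + np.asarray(distances, float), np.full(n, 100.0)])
        return TrackSet(np.stack([a, b]), 1.0, ARENA)

    def test_run_length_example(self):
        ts = self._pair_tracks([45, 39, 38, 41, 36, 50])
        bouts, summary = social_interactions(ts)
        assert [(b.start_frame, b.end_frame) for b in bouts] == [(1, 3), (4, 5)]
        assert summary.loc[0, "social_bout_number"] == 2

    def test_boundary_exactly_forty_is_interaction(self):
        ts = self._pair_tracks([50, 40.0, 50])
        bouts, _ = social_interactions(ts)
        assert len(bouts) == 1

    def test_colocated_flies_one_full_bout_per_pair(self):
        coords = np.tile(np.array([200.0, 200.0]), (3, 60, 1))
        ts = TrackSet(coords, 1.0, ARENA)
        bouts, summary = social_interactions(ts)
        assert len(bouts) == 3  # one per pair
        assert all(b.end_frame - b.start_frame == 60 for b in bouts)

    def test_always_distant_flies_have_no_bouts(self):
        ts = self._pair_tracks([80, 90, 100, 75])
        bouts, summary = social_interactions(ts)
        assert bouts == []
        assert summary["social_bout_number"].sum() == 0

    def test_min_distance_flag_excludes_very_close_frames(self):
        ts = self._pair_tracks([30, 2, 30])
        bouts_default, _ = social_interactions(ts)
        bouts_cut, _ = social_interactions(ts, min_distance_px=5.0)
        assert len(bouts_default) == 1
        assert [(b.start_frame, b.end_frame) for b in bouts_cut] == [(0, 1), (2, 3)]

    def test_single_object_rejected(self):
        ts = TrackSet(np.zeros((1, 10, 2)) + 100.0, 1.0, ARENA)
        with pytest.raises(ValueError):
            social_interactions(ts)

    def test_pair_symmetry(self, short_sim):
        tracks, _, _ = short_sim
        _, summary = social_interactions(tracks)
        # metrics are reported once per unordered pair, i < j
        pairs = set(zip(summary["object_i"], summary["object_j"]))
        assert all(i < j for i, j in pairs)
        assert len(pairs) == tracks.n_objects * (tracks.n_objects - 1) // 2


class TestPerformanceIndex:
    @pytest.mark.parametrize(
        "ref,stim,expected", [(25, 25, 0.0), (50, 0, 1.0), (30, 20, 0.2), (0, 50, -1.0)]
    )
    def test_examples(self, ref, stim, expected):
        assert performance_index(ref, stim) == pytest.approx(expected)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            performance_index(0, 0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(ref=st.integers(0, 100), stim=st.integers(0, 100))
    def test_bounded(self, ref, stim):
        if ref + stim == 0:
            return
        assert -1.0 <= performance_index(ref, stim) <= 1.0


@pytest.fixture(scope="module")
def day_tracks():
    cfg = ArenaConfig(fps=0.5)
    params = BehaviorParams(seed=17)
    tracks, states = simulate_trajectories(cfg, params, 3, 86400.0)
    return tracks, states


class TestMonotonicity:
    def test_sleep_non_decreasing_in_rest_threshold(self, day_tracks):
        tracks, _ = day_tracks
        for i in range(tracks.n_objects):
            totals = []
            for thr in (1.0, 3.0, 6.0, 12.0):
                eps = sleep_episodes(classify_rest(tracks.coords[i], thr), tracks.fps)
                totals.append(sum(e.duration_s for e in eps))
            assert totals == sorted(totals)

    def test_bouts_non_increasing_in_min_duration(self, day_tracks):
        tracks, _ = day_tracks
        for i in range(tracks.n_objects):
            rest = classify_rest(tracks.coords[i])
            counts, totals = [], []
            for mins in (60.0, 300.0, 600.0, 1800.0):
                eps = sleep_episodes(rest, tracks.fps, min_duration_s=mins)
                counts.append(len(eps))
                totals.append(sum(e.duration_s for e in eps))
            assert counts == sorted(counts, reverse=True)
            assert totals == sorted(totals, reverse=True)

    def test_social_non_decreasing_in_threshold(self, day_tracks):
        tracks, _ = day_tracks
        durations = []
        for thr in (10.0, 40.0, 80.0, 160.0):
            _, summary = social_interactions(tracks, interaction_threshold_px=thr)
            durations.append(summary["social_duration_min"].sum())
        assert durations == sorted(durations)


class TestOracleEquivalence:
    def test_daily_summary_matches_state_oracle(self):
        """Metrics from coordinates equal metrics from the generating states."""
        cfg = ArenaConfig(fps=0.5)
        params = BehaviorParams(seed=23)
        tracks, states = simulate_trajectories(cfg, params, 4, 86400.0)
        summary = summarize_behavior(tracks)
        min_frames = min_sleep_frames(cfg.fps)
        for i in range(tracks.n_objects):
            rest_truth = states[i] == STATE_REST
            # independent scan of the ground-truth labels
            runs, run = [], 0
            for flag in rest_truth:
                if flag:
                    run += 1
                else:
                    if run:
                        runs.append(run)
                    run = 0
            if run:
                runs.append(run)
            sleep_frames = sum(r for r in runs if r >= min_frames)
            n_bouts = sum(1 for r in runs if r >= min_frames)
            row = summary.per_object.iloc[i]
            assert row["daily_sleep_min"] == pytest.approx(sleep_frames / cfg.fps / 60.0)
            assert row["bout_number"] == n_bouts

    def test_well_summary_is_mean_over_pairs(self, short_sim):
        tracks, _, _ = short_sim
        _, summary = social_interactions(tracks)
        well = well_social_summary(summary)
        assert well["social_duration_min"] == pytest.approx(
            summary["social_duration_min"].mean()
        )
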