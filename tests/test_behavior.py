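"""Behavioral scoring: speed, freezing, escape, nest time, outcome classes."""

import numpy as np
import pytest

from loomdef import (ArenaConfig, EscapeEvent, SpeedTrace, Trajectory,
                     adaptation_across_trials, classify_outcome, compute_speed,
                     detect_escape, detect_freezing, nest_time,
                     normalized_top_speed, summarize_cohort)
from loomdef.behavior import TrialSummary


def make_traj(xs, ys, fr=20.0):
    n = len(xs)
    return Trajectory(np.arange(n) / fr, np.asarray(xs, float),
                      np.asarray(ys, float), frame_rate_hz=fr)


def make_speed(speeds, fr=20.0, t0=0.0):
    speeds = np.asarray(speeds, float)
    return SpeedTrace(t0 + np.arange(speeds.size) / fr, speeds)


class TestComputeSpeed:
    def test_stationary_animal_zero_speed(self):
        traj = make_traj([10.0] * 50, [10.0] * 50)
        sp = compute_speed(traj)
        assert np.allclose(sp.speed_cm_s, 0.0)

    def test_straight_line_constant_speed(self):
        """1 cm per frame at 20 fps is 20 cm/s everywhere."""
        xs = np.arange(40.0)
        traj = make_traj(xs, np.zeros_like(xs))
        sp = compute_speed(traj)
        assert np.allclose(sp.speed_cm_s, 20.0)

    def test_unsmoothed_matches_pairwise_distance_oracle(self, rng):
        xs = rng.uniform(0, 48, 100)
        ys = rng.uniform(0, 48, 100)
        traj = make_traj(xs, ys)
        sp = compute_speed(traj, smooth_window_s=0.0)
        oracle = np.hypot(np.diff(xs), np.diff(ys)) * 20.0
        assert np.allclose(sp.speed_cm_s, oracle)

    def test_non_monotone_timestamps_raise(self):
        with pytest.raises(ValueError):
            Trajectory(np.array([0.0, 0.1, 0.1]), np.zeros(3), np.zeros(3))


def freezing_oracle(times, speeds, onset, thr=2.0, min_dur=1.0):
    """Brute-force run-length scan over thresholded samples."""
    dt = float(np.median(np.diff(times)))
    episodes = []
    start = None
    for i, (t, v) in enumerate(zip(times, speeds)):
        if t < onset:
            continue
        if v < thr and start is None:
            start = t
        elif v >= thr and start is not None:
            if t - start >= min_dur - 1e-9:
                episodes.append((start, t))
            start = None
    if start is not None:
        end = times[-1] + dt
        if end - start >= min_dur - 1e-9:
            episodes.append((start, end))
    return episodes


class TestDetectFreezing:
    def test_exact_three_second_stop(self):
        # 1 s moving, 3.0 s at zero, then moving again
        v = [5.0] * 20 + [0.0] * 60 + [5.0] * 20
        sp = make_speed(v)
        eps = detect_freezing(sp, stim_onset_s=0.0)
        assert len(eps) == 1
        on, off = eps[0]
        assert off - on == pytest.approx(3.0, abs=1e-9)

    def test_short_episode_rejected(self):
        # 0.9 s below threshold does not qualify
        v = [1.9] * 18 + [5.0] * 30
        eps = detect_freezing(make_speed(v), stim_onset_s=0.0)
        assert eps == []

    def test_pre_onset_stillness_ignored(self):
        v = [0.0] * 40 + [5.0] * 40
        eps = detect_freezing(make_speed(v), stim_onset_s=2.0)
        assert eps == []

    def test_matches_run_length_oracle_on_noisy_traces(self, rng):
        for _ in range(100):
            v = rng.gamma(1.0, 3.0, rng.integers(30, 200))
            sp = make_speed(v)
            onset = float(rng.uniform(0, sp.times_s[-1] / 2))
            got = detect_freezing(sp, onset)
            want = freezing_oracle(sp.times_s, sp.speed_cm_s, onset)
            assert got == pytest.approx(want)

    def test_episodes_maximal_and_subthreshold(self, rng):
        v = rng.gamma(1.0, 3.0, 400)
        sp = make_speed(v)
        eps = detect_freezing(sp, 0.0)
        for on, off in eps:
            inside = (sp.times_s >= on) & (sp.times_s < off)
            assert np.all(sp.speed_cm_s[inside] < 2.0)
            assert off - on >= 1.0 - 1e-9
        for (a, b), (c, d) in zip(eps, eps[1:]):
            assert b < c  # ordered, non-overlapping

    def test_empty_trace_raises(self):
        with pytest.raises(ValueError):
            detect_freezing(SpeedTrace(np.array([]), np.array([])), 0.0)


def escape_scenario(arena, run_speed, baseline_speed=10.0, halt_mid=False):
    """Trajectory: 5 s walking at baseline, then a run to the nest."""
    fr = 20.0
    xs, ys = [], []
    x, y = 30.0, 30.0
    # baseline: pace back and forth at baseline_speed
    direction = 1.0
    for i in range(int(6 * fr)):
        x += direction * baseline_speed / fr
        if x > 40 or x < 24:
            direction *= -1
            x = min(max(x, 24), 40)
        xs.append(x)
        ys.append(y)
    onset = len(xs) / fr
    if halt_mid:
        # run halfway, stop 2 s mid-arena, then continue slowly
        for _ in range(20):
            dx, dy = arena.nest_center[0] - x, arena.nest_center[1] - y
            d = np.hypot(dx, dy)
            x += run_speed / fr * dx / d
            y += run_speed / fr * dy / d
            xs.append(x)
            ys.append(y)
        for _ in range(int(2 * fr)):
            xs.append(x)
            ys.append(y)
        for _ in range(int(3 * fr)):
            xs.append(x)
            ys.append(y)
    else:
        while np.hypot(x - arena.nest_center[0], y - arena.nest_center[1]) > 1.0:
            dx, dy = arena.nest_center[0] - x, arena.nest_center[1] - y
            d = np.hypot(dx, dy)
            x += run_speed / fr * dx / d
            y += run_speed / fr * dy / d
            xs.append(x)
            ys.append(y)
        for _ in range(int(3 * fr)):
            xs.append(x)
            ys.append(y)
    traj = make_traj(xs, ys)
    return traj, compute_speed(traj), onset


class TestDetectEscape:
    def test_fast_run_to_nest_detected(self, arena):
        traj, sp, onset = escape_scenario(arena, run_speed=11.5)
        ev = detect_escape(sp, traj, arena, onset)
        assert ev is not None
        assert ev.top_speed_cm_s >= 11.0

    def test_insufficient_margin_rejected(self, arena):
        """5% above the baseline top speed fails the 10% requirement."""
        traj, sp, onset = escape_scenario(arena, run_speed=10.5)
        assert detect_escape(sp, traj, arena, onset) is None

    def test_halt_mid_arena_rejected(self, arena):
        traj, sp, onset = escape_scenario(arena, run_speed=14.0, halt_mid=True)
        assert detect_escape(sp, traj, arena, onset) is None

    def test_margin_monotonicity(self, arena):
        """Raising the margin can only remove detections, never add them."""
        traj, sp, onset = escape_scenario(arena, run_speed=13.0)
        detected = [detect_escape(sp, traj, arena, onset, margin=m) is not None
                    for m in (0.05, 0.10, 0.20, 0.35, 0.60)]
        assert detected == sorted(detected, reverse=True)

    def test_missing_baseline_raises(self, arena):
        traj, sp, _ = escape_scenario(arena, run_speed=12.0)
        with pytest.raises(ValueError):
            detect_escape(sp, traj, arena, stim_onset_s=1.0)


class TestNormalizedTopSpeed:
    def test_direct_ratio(self):
        v = [10.0] * 100 + [16.0] * 100
        sp = make_speed(v)
        assert normalized_top_speed(sp, (5.0, 10.0)) == pytest.approx(1.6)

    def test_equal_peaks(self):
        v = [10.0] * 200
        assert normalized_top_speed(make_speed(v), (5.0, 10.0)) == pytest.approx(1.0)

    def test_immobile_baseline_raises(self):
        v = [0.0] * 100 + [16.0] * 100
        with pytest.raises(ValueError):
            normalized_top_speed(make_speed(v), (5.0, 10.0))


class TestNestTime:
    def test_whole_window_in_nest(self, arena):
        traj = make_traj([6.0] * 400, [6.0] * 400)
        assert nest_time(traj, arena, 1.0) == pytest.approx(15.0, abs=0.1)

    def test_never_in_refuge(self, arena):
        traj = make_traj([24.0] * 400, [24.0] * 400)
        assert nest_time(traj, arena, 1.0) == 0.0

    def test_enters_after_five_seconds(self, arena):
        fr = 20.0
        xs = [24.0] * int(5 * fr) + [6.0] * int(15 * fr)
        traj = make_traj(xs, xs)
        assert nest_time(traj, arena, 0.0) == pytest.approx(10.0, abs=0.1)

    def test_corner_counts_as_refuge(self, arena):
        # far corner, outside the nest disc but inside a corner zone
        traj = make_traj([45.0] * 400, [45.0] * 400)
        assert nest_time(traj, arena, 1.0) == pytest.approx(15.0, abs=0.1)

    def test_additive_over_window_split(self, arena, rng):
        xs = rng.uniform(0, 48, 500)
        ys = rng.uniform(0, 48, 500)
        traj = make_traj(xs, ys)
        full = nest_time(traj, arena, 2.0, window_s=15.0)
        for split in (3.0, 7.5, 12.0):
            a = nest_time(traj, arena, 2.0, window_s=split - 2.0)
            b = nest_time(traj, arena, split, window_s=17.0 - split)
            assert a + b == pytest.approx(full, abs=1e-9)


class TestClassifyOutcome:
    def test_freezing_then_escape(self):
        ev = EscapeEvent(onset_s=3.5, latency_s=3.5, top_speed_cm_s=20.0)
        assert classify_outcome([(0.5, 3.5)], ev) == "freezing_escape"

    def test_escape_without_freezing(self):
        ev = EscapeEvent(onset_s=0.4, latency_s=0.4, top_speed_cm_s=20.0)
        assert classify_outcome([], ev) == "escape_only"

    def test_freezing_only_and_none(self):
        assert classify_outcome([(0.5, 4.0)], None) == "freezing_only"
        assert classify_outcome([], None) == "none"

    def test_escape_inside_episode_raises(self):
        ev = EscapeEvent(onset_s=2.0, latency_s=2.0, top_speed_cm_s=20.0)
        with pytest.raises(ValueError):
            classify_outcome([(0.5, 4.0)], ev)


def trial(outcome, freeze=None, latency=None, nts=None, nest=0.0):
    return TrialSummary(freezing_duration_s=freeze, freezing_onset_s=None,
                        escape_latency_s=latency, normalized_top_speed=nts,
                        nest_time_s=nest, outcome=outcome)


class TestCohortSummaries:
    def test_outcome_percentages_printed_counts(self):
        """5/9 freezing -> 56%, 4/9 escaping -> 44% to the nearest percent."""
        trials = ([trial("freezing_escape")] * 4 + [trial("freezing_only")]
                  + [trial("none")] * 4)
        cs = summarize_cohort(trials)
        n_freezing = (cs.outcome_counts["freezing_escape"]
                      + cs.outcome_counts["freezing_only"])
        assert round(100 * n_freezing / cs.n) == 56
        n_escaping = (cs.outcome_counts["freezing_escape"]
                      + cs.outcome_counts["escape_only"])
        assert round(100 * n_escaping / cs.n) == 44

    def test_mean_sem_degenerate(self):
        cs = summarize_cohort([trial("none", freeze=3.0)] * 3)
        assert cs.means["freezing_duration_s"] == pytest.approx(3.0)
        assert cs.sems["freezing_duration_s"] == 0.0

    def test_missing_values_excluded_with_count(self):
        trials = [trial("freezing_only", freeze=2.0),
                  trial("escape_only", latency=1.0),
                  trial("none")]
        cs = summarize_cohort(trials)
        assert cs.counts["freezing_duration_s"] == 1
        assert cs.counts["escape_latency_s"] == 1

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError):
            summarize_cohort([])


class TestAdaptationAcrossTrials:
    def test_all_freeze_first_none_last(self):
        seqs = [[trial("freezing_escape")] * 4 + [trial("none")]
                for _ in range(6)]
        df = adaptation_across_trials(seqs)
        assert df["p_freezing"].tolist() == [1.0, 1.0, 1.0, 1.0, 0.0]

    def test_probabilities_bounded(self, rng):
        outcomes = ["freezing_escape", "escape_only", "freezing_only", "none"]
        seqs = [[trial(outcomes[rng.integers(4)]) for _ in range(5)]
                for _ in range(10)]
        df = adaptation_across_trials(seqs)
        for col in ("p_freezing", "p_escape"):
            assert ((df[col] >= 0) & (df[col] <= 1)).all()

    def test_printed_adaptation_counts(self):
        """A 9-animal cohort built from the printed trial-1/trial-2 counts
        reproduces 56%/33% freezing and 100%/44% escape probabilities."""
        seqs = []
        for i in range(9):
            t1 = trial("freezing_escape") if i < 5 else trial("escape_only")
            if i < 3:
                t2 = trial("freezing_escape")
            elif i < 4:
                t2 = trial("escape_only")
            else:
                t2 = trial("none")
        # trial-2 escape count must be 4: three freezing-escape + one escape-only
            seqs.append([t1, t2])
        df = adaptation_across_trials(seqs)
        assert round(100 * df["p_freezing"][0]) == 56
        assert round(100 * df["p_freezing"][1]) == 33
        assert round(100 * df["p_escape"][0]) == 100
        assert round(100 * df["p_escape"][1]) == 44
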