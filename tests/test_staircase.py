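"""Staircase mechanics, threshold estimation and observer behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppaudit._rng import child_rng
from ppaudit.staircase import (StaircaseState, StaircaseTrack, VirtualObserver,
                               convergence_level, estimate_threshold,
                               observer_respond, run_adaptive, run_fixed,
                               staircase_update)


def make_state(level=10.0):
    return StaircaseState(level=level, floor=0.01, ceiling=100.0)


class TestUpdateRule:
    def test_two_correct_steps_down(self):
        s = make_state(10.0)
        s = staircase_update(s, True)
        assert s.level == 10.0 and s.consecutive_correct == 1
        s = staircase_update(s, True)
        assert s.level == pytest.approx(5.0)
        assert s.consecutive_correct == 0

    def test_one_incorrect_steps_up(self):
        s = staircase_update(make_state(10.0), False)
        assert s.level == pytest.approx(20.0)

    def test_reversals_recorded_on_direction_flip(self):
        s = make_state(10.0)
        for correct in (True, True, False):  # down then up: one reversal
            s = staircase_update(s, correct)
        assert len(s.reversal_levels) == 1
        assert s.reversal_levels[0] == pytest.approx(5.0)

    def test_step_refines_after_second_reversal(self):
        s = make_state(10.0)
        # down, up, down-down -> two reversals -> sqrt(2) steps afterwards
        for correct in (True, True, False, True, True):
            s = staircase_update(s, correct)
        assert len(s.reversal_levels) == 2
        assert s.step_factor == pytest.approx(math.sqrt(2.0))

    def test_repeating_pattern_oscillates_with_growing_reversals(self):
        s = make_state(10.0)
        counts = []
        for _ in range(60):
            s = staircase_update(s, True)
            s = staircase_update(s, True)
            s = staircase_update(s, False)
            counts.append(len(s.reversal_levels))
            assert s.floor <= s.level <= s.ceiling
        assert counts[-1] > counts[10] > 0

    def test_levels_clipped_to_bounds(self):
        s = make_state(90.0)
        for _ in range(5):
            s = staircase_update(s, False)
        assert s.level == 100.0


class TestThresholdEstimate:
    def test_constant_reversals(self):
        assert estimate_threshold([3.0] * 6) == (pytest.approx(3.0), True)

    def test_geometric_mean_of_alternating_reversals(self):
        thr, ok = estimate_threshold([8, 4, 8, 4, 8, 4])
        assert ok
        assert thr == pytest.approx(math.sqrt(32.0))

    def test_too_few_reversals_flagged(self):
        thr, ok = estimate_threshold([5.0, 6.0, 7.0])
        assert not ok and math.isnan(thr)

    def test_empty_track_errors(self):
        track = StaircaseTrack("p1", [], [], [], [], float("nan"), False)
        with pytest.raises(ValueError, match="empty"):
            estimate_threshold(track)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_equivariance(self, k):
        revs = [8.0, 4.0, 6.0, 3.0, 5.0, 4.5]
        base, _ = estimate_threshold(revs)
        scaled, _ = estimate_threshold([k * r for r in revs])
        assert scaled == pytest.approx(k * base, rel=1e-9)


class TestObserver:
    def test_psychometric_midpoint(self):
        obs = VirtualObserver(threshold=2.0, slope=5.0, lapse=0.0, guess=0.5)
        assert obs.p_correct(2.0) == pytest.approx(0.75)
        assert obs.p_correct(1e9) == pytest.approx(1.0, abs=1e-6)
        assert obs.p_correct(0.0) == 0.5

    def test_empirical_rate_matches_closed_form(self):
        obs = VirtualObserver(threshold=1.0, slope=4.0, lapse=0.02, guess=0.5)
        delta = 1.6
        g = child_rng(42)
        n = 10_000
        hits = sum(observer_respond(obs, delta, g) for _ in range(n))
        p = obs.p_correct(delta)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 2 * se + 1e-9

    def test_invalid_observers_rejected(self):
        with pytest.raises(ValueError):
            VirtualObserver(threshold=-1.0)
        with pytest.raises(ValueError):
            VirtualObserver(threshold=1.0, lapse=0.5)


class TestAdaptiveRuns:
    def test_same_seed_identical_tracks(self):
        obs = VirtualObserver(threshold=0.5, guess=0.5)
        a = run_adaptive("p1", obs, 7)
        b = run_adaptive("p1", obs, 7)
        assert a.levels == b.levels and a.responses == b.responses
        assert a.threshold == b.threshold

    def test_always_correct_descends_to_floor(self):
        obs = VirtualObserver(threshold=1e-6, slope=50.0, lapse=0.0, guess=0.5)
        track = run_adaptive("p1", obs, 1)
        diffs = np.diff(track.levels)
        assert np.all(diffs <= 1e-12)
        assert track.levels[-1] == pytest.approx(0.01)  # task floor
        assert not track.converged  # no reversals on a monotone descent

    def test_guess_rate_mismatch_rejected(self):
        obs = VirtualObserver(threshold=10.0, guess=0.5)
        with pytest.raises(ValueError, match="guess rate"):
            run_adaptive("r3", obs, 0)  # r3 is 3AFC

    def test_convergence_to_707_point(self):
        """Mean estimated threshold approaches the 70.7%-correct level."""
        obs = VirtualObserver(threshold=20.0, slope=6.0, lapse=0.0, guess=0.5)
        target = convergence_level(obs)
        thr = [run_adaptive("r1", obs, child_rng(s, 3)).threshold for s in range(50)]
        thr = [t for t in thr if not math.isnan(t)]
        est = math.exp(np.mean(np.log(thr)))
        assert abs(est - target) / target < 0.15

    def test_plateau_after_initial_descent(self):
        """Median absolute level change shrinks in the second half of a run."""
        early, late = [], []
        for s in range(30):
            obs = VirtualObserver(threshold=float(np.exp(np.random.default_rng(s)
                                                         .normal(np.log(0.4), 0.8))),
                                  guess=0.5)
            tr = run_adaptive("p1", obs, child_rng(s, 9))
            lv = np.log(tr.levels)
            early.append(np.mean(np.abs(np.diff(lv[:25]))))
            late.append(np.mean(np.abs(np.diff(lv[25:]))))
        # early trials include the coarse factor-2 descent; after the plateau
        # only fine steps remain, so the typical level change shrinks
        assert np.median(late) < np.median(early)


class TestFixedRuns:
    def test_perfect_observer_scores_40(self):
        obs = VirtualObserver(threshold=1e-6, slope=50.0, lapse=0.0, guess=0.5)
        score, log = run_fixed("p3", obs, 0)
        assert score == 40
        assert len(log) == 40

    def test_non_perceiving_observer_scores_at_guessing_level(self):
        obs = VirtualObserver(threshold=1e9, slope=50.0, lapse=0.0, guess=0.5)
        score, _ = run_fixed("p3", obs, 1)
        assert score == 20  # all 'same' correct, all 'different' missed

    def test_balanced_same_different_design(self):
        obs = VirtualObserver(threshold=0.8, slope=3.0, guess=0.5)
        for s in range(5):
            _, log = run_fixed("p4", obs, s)
            n_diff = sum(e["different"] for e in log)
            assert n_diff == 20 and len(log) == 40
            refs = [e["reference"] for e in log]
            assert sorted(refs) == sorted(list(range(20)) * 2)

    def test_adaptive_task_rejected(self):
        obs = VirtualObserver(threshold=1.0, guess=0.5)
        with pytest.raises(ValueError, match="fixed"):
            run_fixed("p1", obs, 0)
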