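"""Battery structure, stimulus synthesis and trial construction."""

import numpy as np
import pytest

from ppaudit.battery import (LOG_TASKS, TASK_IDS, ModulationSpec, SequenceSpec,
                             ToneSpec, build_battery, contour,
                             make_pitch_sequence_trial, make_pitch_trial,
                             make_rhythm_trial, semitone_shift, synth_modulated,
                             synth_pure_tone)


def rng(seed=0):
    return np.random.default_rng(seed)


class TestBatteryStructure:
    def test_twelve_tasks_four_per_domain(self):
        battery = build_battery()
        assert len(battery) == 12
        assert tuple(t.task_id for t in battery) == TASK_IDS
        domains = [t.domain for t in battery]
        assert domains.count("pitch") == domains.count("rhythm") == \
            domains.count("timbre") == 4

    def test_paradigms_and_trial_counts(self):
        by_id = {t.task_id: t for t in build_battery()}
        for tid in ("p3", "p4"):
            assert by_id[tid].paradigm == "fixed_same_different"
            assert by_id[tid].n_trials == 40
        for tid in set(TASK_IDS) - {"p3", "p4"}:
            assert by_id[tid].is_adaptive
            assert by_id[tid].n_trials == 50
        # 3AFC tasks carry the 1/3 guess rate, 2AFC tasks 0.5
        for tid in ("r3", "r4", "m4"):
            assert by_id[tid].guess_rate == pytest.approx(1 / 3)
        assert by_id["p1"].guess_rate == 0.5

    def test_log_transform_registry(self):
        flagged = {t.task_id for t in build_battery() if t.log_transform_outcome}
        assert flagged == set(LOG_TASKS) == {"p1", "r1", "r2", "m2", "m3"}


class TestToneSynthesis:
    def test_sample_counts(self):
        assert len(synth_pure_tone(ToneSpec(500, 100), 44100)) == 4410
        assert len(synth_pure_tone(ToneSpec(500, 250), 44100)) == 11025

    def test_rms_of_unramped_sinusoid(self):
        w = synth_pure_tone(ToneSpec(500, 1000, level_db=0.0, ramp_ms=0.0), 44100)
        assert np.sqrt(np.mean(w**2)) == pytest.approx(1 / np.sqrt(2), abs=1e-3)
        assert np.max(np.abs(w)) <= 1.0

    def test_aliasing_rejected(self):
        with pytest.raises(ValueError, match="sample rate"):
            synth_pure_tone(ToneSpec(500, 100), 1000)

    def test_invalid_tone_specs(self):
        with pytest.raises(ValueError):
            ToneSpec(-1, 100)
        with pytest.raises(ValueError):
            ToneSpec(500, 100, ramp_ms=60)


class TestPitchTrials:
    def test_semitone_arithmetic(self):
        assert semitone_shift(500, 1) == pytest.approx(529.73, abs=0.01)
        trial = make_pitch_trial("p1", 1.0, rng(), reference_hz=500.0)
        changed = trial["pairs_hz"][trial["target_index"]]
        assert abs(changed[1] / changed[0]) == pytest.approx(2 ** (1 / 12)) or \
            abs(changed[1] / changed[0]) == pytest.approx(2 ** (-1 / 12))

    def test_zero_delta_undecidable(self):
        trial = make_pitch_trial("p1", 0.0, rng())
        assert trial["undecidable"]
        assert trial["pairs_hz"][0] == trial["pairs_hz"][1]

    def test_direction_agreement_labels(self):
        seen = set()
        for s in range(50):
            trial = make_pitch_trial("p2", 2.0, rng(s))
            d1, d2 = trial["directions"]
            assert trial["answer"] == ("same" if d1 == d2 else "different")
            seen.add(trial["answer"])
        assert seen == {"same", "different"}

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            make_pitch_trial("p1", -1.0, rng())


class TestPitchSequences:
    @pytest.mark.parametrize("task_id", ["p3", "p4"])
    def test_same_trials_identical(self, task_id):
        trial = make_pitch_sequence_trial(task_id, same=True, rng=rng(3))
        assert trial["reference"].frequencies == trial["comparison"].frequencies

    def test_local_change_preserves_contour(self):
        g = rng(1)
        for _ in range(300):
            trial = make_pitch_sequence_trial("p3", same=False, rng=g)
            ref, cmp_ = trial["reference"].frequencies, trial["comparison"].frequencies
            assert contour(ref) == contour(cmp_)
            assert ref != cmp_
            k = trial["changed_index"]
            assert ref[k] != cmp_[k]

    def test_global_change_breaks_contour(self):
        g = rng(2)
        for _ in range(300):
            trial = make_pitch_sequence_trial("p4", same=False, rng=g)
            assert contour(trial["reference"].frequencies) != \
                contour(trial["comparison"].frequencies)


class TestRhythmTrials:
    def test_isochrony_deviation_arithmetic(self):
        trial = make_rhythm_trial("r2", 400.0, 25.0, rng(0))
        target = trial["sequences"][trial["answer"]]
        assert target.iois_ms == pytest.approx((400.0, 400.0, 500.0, 400.0))
        other = trial["sequences"][1 - trial["answer"]]
        assert other.iois_ms == pytest.approx((400.0,) * 4)
        # total lengthening is exactly ref_ioi * delta / 100
        assert target.total_duration_ms - other.total_duration_ms == \
            pytest.approx(100.0, abs=1e-9)

    def test_zero_delta_pairs_identical(self):
        trial = make_rhythm_trial("r1", 450.0, 0.0, rng(0))
        assert trial["undecidable"]
        assert trial["pairs"][0].onsets_ms == trial["pairs"][1].onsets_ms

    def test_reference_range_enforced(self):
        with pytest.raises(ValueError, match="300"):
            make_rhythm_trial("r2", 250.0, 10.0, rng(0))

    @pytest.mark.parametrize("task_id", ["r3", "r4"])
    def test_metrical_distortion(self, task_id):
        trial = make_rhythm_trial(task_id, 400.0, 30.0, rng(5))
        ref = np.array(trial["reference"].onsets_ms)
        dist = np.array(trial["comparisons"][trial["answer"]].onsets_ms)
        assert np.sum(ref != dist) == 1  # exactly one displaced onset
        assert len(ref) == 7
        d = np.diff(dist)
        assert np.all(d > 0)  # tones stay ordered and non-overlapping


class TestModulation:
    def test_zero_depth_reproduces_pure_tone(self):
        w = synth_modulated("m1", ModulationSpec(fm_rate=2.0, fm_depth=0.0))
        n = len(w)
        t = np.arange(n) / 44100.0
        expected = 0.5 * np.sin(2 * np.pi * 500.0 * t)
        ramp = w[4410:-4410] - expected[4410:-4410]  # compare the steady part
        assert np.max(np.abs(ramp)) < 1e-9

    def test_fm_sidebands_at_modulation_rate(self):
        w = synth_modulated("m2", ModulationSpec(fm_rate=40.0, fm_depth=0.05))
        spec = np.abs(np.fft.rfft(w))
        freqs = np.fft.rfftfreq(len(w), 1 / 44100.0)
        def power_at(f):
            return spec[np.argmin(np.abs(freqs - f))]
        baseline = np.median(spec)
        assert power_at(460) > 20 * baseline
        assert power_at(540) > 20 * baseline

    def test_modulation_durations_and_bounds(self):
        for tid, rate in (("m1", 2.0), ("m2", 40.0), ("m3", 4.0), ("m4", 4.0)):
            w = synth_modulated(tid, ModulationSpec(fm_rate=rate, fm_depth=0.1))
            assert len(w) == 44100  # 1000 ms at 44.1 kHz
            assert np.max(np.abs(w)) <= 1.0

    def test_wrong_fm_rate_rejected(self):
        with pytest.raises(ValueError, match="Hz"):
            synth_modulated("m1", ModulationSpec(fm_rate=7.0, fm_depth=0.1))


def test_sequence_spec_invariants():
    tone = ToneSpec(500, 100)
    with pytest.raises(ValueError):
        SequenceSpec((tone, tone), (0.0, 0.0))
    seq = SequenceSpec((tone, tone, tone), (0.0, 300.0, 600.0))
    assert seq.iois_ms == (300.0, 300.0)
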