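"""The 12-task psychoacoustic battery: pitch, rhythm/timing and timbre.

Four tasks per domain. Ten tasks are adaptive forced-choice tasks whose
outcome is a discrimination threshold; the two pitch-sequence tasks (p3,
p4) run at a fixed difficulty and score the number of correct
same/different judgements out of 40.

Tasks and their difficulty dimensions
-------------------------------------
p1  pitch change detection               (semitones)     adaptive 2AFC
p2  pitch change-direction discrimination(semitones)     adaptive 2AFC
p3  local pitch-sequence change          (semitones)     fixed same/different
p4  global pitch-sequence (contour) change (semitones)   fixed same/different
r1  single time-interval discrimination  (% IOI)         adaptive 2AFC
r2  isochrony deviation detection        (% IOI)         adaptive 2AFC
r3  strongly metrical pattern discrimination (% beat)    adaptive 3AFC (XAB)
r4  weakly metrical pattern discrimination   (% beat)    adaptive 3AFC (XAB)
m1  2 Hz FM detection                    (depth fraction) adaptive 2AFC
m2  40 Hz FM detection                   (depth fraction) adaptive 2AFC
m3  dynamic (spectro-temporal) modulation detection (depth) adaptive 2AFC
m4  dynamic modulation discrimination    (cyc/oct)       adaptive 3AFC (AXB)

All analysis operates on parametric trial descriptors; waveform synthesis
(`synth_pure_tone`, `synth_modulated`, `render_sequence`) exists for
inspection and WAV export only.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ToneSpec",
    "SequenceSpec",
    "ModulationSpec",
    "TaskDefinition",
    "TASK_IDS",
    "LOG_TASKS",
    "SCORE_TASKS",
    "build_battery",
    "get_task",
    "battery_to_json",
    "semitone_shift",
    "contour",
    "synth_pure_tone",
    "synth_modulated",
    "render_sequence",
    "make_pitch_trial",
    "make_pitch_sequence_trial",
    "make_rhythm_trial",
    "export_wav",
]

TASK_IDS = ("p1", "p2", "p3", "p4", "r1", "r2", "r3", "r4", "m1", "m2", "m3", "m4")

#: tasks whose outcome distribution is log-normal across subjects and is
#: log-transformed by the group-level transform policy
LOG_TASKS = frozenset({"p1", "r1", "r2", "m2", "m3"})

#: fixed-difficulty tasks whose outcome is a score correct /40 (lower = worse);
#: every other task's outcome is a threshold (higher = worse)
SCORE_TASKS = frozenset({"p3", "p4"})


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToneSpec:
    """A single pure tone: frequency (Hz), duration (ms), level (dB re FS),
    and raised-cosine onset/offset ramp (ms)."""

    frequency: float
    duration_ms: float
    level_db: float = -6.0
    ramp_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.duration_ms <= 0:
            raise ValueError("duration must be positive")
        if 2 * self.ramp_ms > self.duration_ms:
            raise ValueError("onset+offset ramps exceed tone duration")


@dataclass(frozen=True)
class SequenceSpec:
    """An ordered tone sequence with onset times (ms from sequence start)."""

    tones: tuple[ToneSpec, ...]
    onsets_ms: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.tones) != len(self.onsets_ms):
            raise ValueError("one onset per tone required")
        d = np.diff(self.onsets_ms)
        if len(d) and np.any(d <= 0):
            raise ValueError("onsets must be strictly increasing")

    @property
    def iois_ms(self) -> tuple[float, ...]:
        return tuple(float(x) for x in np.diff(self.onsets_ms))

    @property
    def total_duration_ms(self) -> float:
        return float(self.onsets_ms[-1] + self.tones[-1].duration_ms)

    @property
    def frequencies(self) -> tuple[float, ...]:
        return tuple(t.frequency for t in self.tones)


@dataclass(frozen=True)
class ModulationSpec:
    """Parameters of an FM tone or a dynamic-ripple sound.

    ``fm_depth`` is the peak frequency excursion as a fraction of the
    carrier; ``ripple_density`` is in cycles/octave and ``ripple_rate``
    in Hz. Modulation-task stimuli last 1000 ms.
    """

    carrier: float = 500.0
    fm_rate: float = 2.0
    fm_depth: float = 0.0
    ripple_density: float = 1.0
    ripple_rate: float = 4.0
    ripple_depth: float = 1.0
    duration_ms: float = 1000.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fm_depth <= 1.0:
            raise ValueError("fm_depth must lie in [0, 1]")
        if self.carrier <= 0 or self.duration_ms <= 0:
            raise ValueError("carrier and duration must be positive")


@dataclass(frozen=True)
class TaskDefinition:
    """Static description of one battery task, including the staircase
    bookkeeping the adaptive engine needs (start level, floor, ceiling)."""

    task_id: str
    domain: str  # pitch | rhythm | timbre
    paradigm: str  # adaptive_2AFC | adaptive_3AFC | fixed_same_different
    n_trials: int
    difficulty_dimension: str
    difficulty_units: str
    log_transform_outcome: bool
    guess_rate: float
    start_level: float
    floor: float
    ceiling: float
    fixed_delta: float | None = None  # difficulty of fixed same/different tasks
    higher_is_worse: bool = True  # thresholds: yes; scores correct: no

    @property
    def is_adaptive(self) -> bool:
        return self.paradigm.startswith("adaptive")


def _tasks() -> list[TaskDefinition]:
    A2, A3, FX = "adaptive_2AFC", "adaptive_3AFC", "fixed_same_different"
    t = [
        TaskDefinition("p1", "pitch", A2, 50, "frequency change", "semitones",
                       True, 0.5, 4.0, 0.01, 12.0),
        TaskDefinition("p2", "pitch", A2, 50, "frequency-change size for direction judgement",
                       "semitones", False, 0.5, 4.0, 0.01, 12.0),
        TaskDefinition("p3", "pitch", FX, 40, "altered-tone frequency change (contour preserved)",
                       "semitones", False, 0.5, 1.0, 0.01, 12.0, fixed_delta=1.0,
                       higher_is_worse=False),
        TaskDefinition("p4", "pitch", FX, 40, "altered-tone frequency change (contour violated)",
                       "semitones", False, 0.5, 1.0, 0.01, 12.0, fixed_delta=1.0,
                       higher_is_worse=False),
        TaskDefinition("r1", "rhythm", A2, 50, "interval lengthening", "% IOI",
                       True, 0.5, 60.0, 0.5, 100.0),
        TaskDefinition("r2", "rhythm", A2, 50, "isochrony deviation", "% IOI",
                       True, 0.5, 60.0, 0.5, 100.0),
        TaskDefinition("r3", "rhythm", A3, 50, "onset displacement, strongly metrical",
                       "% beat", False, 1.0 / 3.0, 55.0, 1.0, 80.0),
        TaskDefinition("r4", "rhythm", A3, 50, "onset displacement, weakly metrical",
                       "% beat", False, 1.0 / 3.0, 55.0, 1.0, 80.0),
        TaskDefinition("m1", "timbre", A2, 50, "2 Hz FM depth", "fraction of carrier",
                       False, 0.5, 0.2, 1e-4, 0.5),
        TaskDefinition("m2", "timbre", A2, 50, "40 Hz FM depth", "fraction of carrier",
                       True, 0.5, 0.2, 1e-4, 0.5),
        TaskDefinition("m3", "timbre", A2, 50, "dynamic modulation depth", "fraction",
                       True, 0.5, 0.8, 1e-3, 1.0),
        TaskDefinition("m4", "timbre", A3, 50, "spectral density difference", "cyc/oct",
                       False, 1.0 / 3.0, 2.5, 0.05, 4.0),
    ]
    return t


def build_battery() -> list[TaskDefinition]:
    """Return the 12 task definitions (4 per domain, in canonical order)."""
    battery = _tasks()
    assert tuple(t.task_id for t in battery) == TASK_IDS
    return battery


def get_task(task_id: str) -> TaskDefinition:
    for t in _tasks():
        if t.task_id == task_id:
            return t
    raise KeyError(f"unknown task id: {task_id!r}")


def battery_to_json(battery: Sequence[TaskDefinition] | None = None, indent: int = 2) -> str:
    """Serialize the battery as a JSON array of task objects."""
    battery = list(battery) if battery is not None else build_battery()
    return json.dumps([asdict(t) for t in battery], indent=indent)


# ---------------------------------------------------------------------------
# elementary synthesis
# ---------------------------------------------------------------------------


def semitone_shift(frequency: float, semitones: float) -> float:
    """Frequency shifted by a signed number of semitones (12-TET)."""
    return float(frequency * 2.0 ** (semitones / 12.0))


def contour(frequencies: Sequence[float]) -> str:
    """Up/down pattern of a tone sequence, e.g. ``'+-+'``.

    ``'0'`` marks a repeated frequency (should not occur in generated
    sequences, but is preserved rather than hidden).
    """
    out = []
    for a, b in zip(frequencies[:-1], frequencies[1:]):
        out.append("+" if b > a else "-" if b < a else "0")
    return "".join(out)


def _ramp_envelope(n: int, n_ramp: int) -> np.ndarray:
    env = np.ones(n)
    if n_ramp > 0:
        r = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] = r
        env[-n_ramp:] = r[::-1]
    return env


def synth_pure_tone(spec: ToneSpec, sample_rate: float = 44100.0) -> np.ndarray:
    """Render a pure tone with raised-cosine onset/offset ramps.

    Peak amplitude is ``10**(level_db/20)`` (≤ 1). The sample rate must be
    at least four times the tone frequency to stay comfortably clear of
    aliasing.
    """
    if sample_rate < 4.0 * spec.frequency:
        raise ValueError(
            f"sample rate {sample_rate} Hz too low for a {spec.frequency} Hz tone "
            "(need ≥ 4× the frequency)"
        )
    n = int(round(spec.duration_ms / 1000.0 * sample_rate))
    t = np.arange(n) / sample_rate
    peak = 10.0 ** (spec.level_db / 20.0)
    y = peak * np.sin(2.0 * np.pi * spec.frequency * t)
    return y * _ramp_envelope(n, int(round(spec.ramp_ms / 1000.0 * sample_rate)))


def synth_modulated(task_id: str, spec: ModulationSpec,
                    sample_rate: float = 44100.0) -> np.ndarray:
    """Render a modulation-task stimulus.

    m1/m2: sinusoidal FM about the carrier at 2 or 40 Hz; ``fm_depth`` 0
    reproduces the unmodulated carrier sample-for-sample. m3/m4: a dynamic
    ripple — a bank of log-spaced carriers whose spectral envelope drifts
    sinusoidally over time; ``ripple_depth`` 0 reproduces the flat
    (unmodulated) carrier bank.
    """
    n = int(round(spec.duration_ms / 1000.0 * sample_rate))
    t = np.arange(n) / sample_rate
    if task_id in ("m1", "m2"):
        expected = {"m1": 2.0, "m2": 40.0}[task_id]
        if spec.fm_rate != expected:
            raise ValueError(f"{task_id} uses a {expected:g} Hz modulation rate")
        # peak frequency excursion = fm_depth * carrier
        beta = spec.fm_depth * spec.carrier / spec.fm_rate  # modulation index
        phase = 2.0 * np.pi * spec.carrier * t + beta * np.sin(2.0 * np.pi * spec.fm_rate * t)
        y = 0.5 * np.sin(phase)
    elif task_id in ("m3", "m4"):
        f_lo, f_hi, n_comp = 250.0, 4000.0, 48
        freqs = f_lo * (f_hi / f_lo) ** (np.arange(n_comp) / (n_comp - 1))
        octaves = np.log2(freqs / f_lo)
        # deterministic per-component phases decorrelate the carriers
        phases = 2.0 * np.pi * np.arange(n_comp) * 0.37
        y = np.zeros(n)
        for f, x, ph in zip(freqs, octaves, phases):
            env = 1.0 + spec.ripple_depth * np.sin(
                2.0 * np.pi * (spec.ripple_rate * t + spec.ripple_density * x)
            )
            y += env * np.sin(2.0 * np.pi * f * t + ph)
        y /= np.max(np.abs(y)) / 0.9 + 1e-12
    else:
        raise ValueError(f"{task_id!r} is not a modulation task")
    return y * _ramp_envelope(n, int(round(10e-3 * sample_rate)))


def render_sequence(seq: SequenceSpec, sample_rate: float = 44100.0) -> np.ndarray:
    """Mix a tone sequence into a single waveform (clipped to [-1, 1])."""
    n = int(round(seq.total_duration_ms / 1000.0 * sample_rate))
    y = np.zeros(n)
    for tone, onset in zip(seq.tones, seq.onsets_ms):
        w = synth_pure_tone(tone, sample_rate)
        i = int(round(onset / 1000.0 * sample_rate))
        y[i : i + len(w)] += w
    return np.clip(y, -1.0, 1.0)


def export_wav(path, waveform: np.ndarray, sample_rate: int = 44100) -> None:
    """Write a waveform as 16-bit PCM RIFF."""
    from scipy.io import wavfile

    data = np.asarray(waveform, dtype=float)
    wavfile.write(path, int(sample_rate), (np.clip(data, -1, 1) * 32767).astype(np.int16))


# ---------------------------------------------------------------------------
# trial construction
# ---------------------------------------------------------------------------


def make_pitch_trial(task_id: str, delta_semitones: float,
                     rng: np.random.Generator, reference_hz: float | None = None) -> dict:
    """Build a single p1 or p2 trial descriptor.

    p1: two AB tone pairs; one pair is flat, the other contains an up-or-
    down change of ``delta_semitones``; the answer is the changed pair's
    index. p2: both pairs change by ``delta_semitones``; the answer is
    'same' or 'different' according to direction agreement.
    """
    if task_id not in ("p1", "p2"):
        raise ValueError("make_pitch_trial handles p1/p2 only")
    if delta_semitones < 0:
        raise ValueError("delta must be non-negative")
    f0 = reference_hz if reference_hz is not None else float(rng.uniform(440.0, 560.0))

    def pair(direction: int) -> tuple[float, float]:
        return (f0, semitone_shift(f0, direction * delta_semitones))

    if task_id == "p1":
        target = int(rng.integers(2))
        direction = int(rng.choice((-1, 1)))
        pairs = [pair(0), pair(0)]
        pairs[target] = pair(direction)
        return {
            "task_id": "p1",
            "pairs_hz": tuple(pairs),
            "target_index": target,
            "answer": target,
            "delta_semitones": delta_semitones,
            "undecidable": delta_semitones == 0.0,
        }
    d1, d2 = (int(rng.choice((-1, 1))) for _ in range(2))
    return {
        "task_id": "p2",
        "pairs_hz": (pair(d1), pair(d2)),
        "directions": (d1, d2),
        "answer": "same" if d1 == d2 else "different",
        "delta_semitones": delta_semitones,
        "undecidable": delta_semitones == 0.0,
    }


def _four_tone_positions(rng: np.random.Generator) -> np.ndarray:
    """Random 4-tone melody as semitone positions, inter-tone steps ±1–3 st."""
    steps = rng.choice((1, 2, 3), size=3) * rng.choice((-1, 1), size=3)
    return np.concatenate(([0.0], np.cumsum(steps.astype(float))))


def _positions_to_sequence(pos: np.ndarray, base_hz: float) -> SequenceSpec:
    tones = tuple(ToneSpec(semitone_shift(base_hz, p), 250.0) for p in pos)
    onsets = tuple(300.0 * i for i in range(len(pos)))
    return SequenceSpec(tones, onsets)


def make_pitch_sequence_trial(task_id: str, same: bool,
                              rng: np.random.Generator) -> dict:
    """Build a p3 (local) or p4 (global) same/different sequence trial.

    'Different' trials alter the 3rd or 4th tone; for p3 the altered
    sequence keeps the reference's up/down contour, for p4 the contour
    changes at the altered transition. The altered tone moves by roughly
    the requested step inventory (1–3 semitones on a semitone grid).
    """
    if task_id not in ("p3", "p4"):
        raise ValueError("make_pitch_sequence_trial handles p3/p4 only")
    base_hz = float(rng.uniform(440.0, 560.0))
    for _ in range(100):
        pos = _four_tone_positions(rng)
        if same:
            ref = _positions_to_sequence(pos, base_hz)
            return {"task_id": task_id, "reference": ref, "comparison": ref,
                    "answer": "same", "changed_index": None}
        k = int(rng.choice((2, 3)))
        cand = _alteration_candidates(pos, k, preserve=(task_id == "p3"))
        if not cand:
            k = 5 - k  # try the other alterable tone
            cand = _alteration_candidates(pos, k, preserve=(task_id == "p3"))
        if cand:
            new = pos.copy()
            new[k] = float(rng.choice(cand))
            return {
                "task_id": task_id,
                "reference": _positions_to_sequence(pos, base_hz),
                "comparison": _positions_to_sequence(new, base_hz),
                "answer": "different",
                "changed_index": k,
            }
    raise RuntimeError("failed to construct a valid sequence trial")  # pragma: no cover


def _alteration_candidates(pos: np.ndarray, k: int, preserve: bool) -> list[float]:
    """Semitone-grid values for tone ``k`` that keep (p3) or break (p4) the
    contour while leaving all intervals non-zero."""
    grid = [pos[k] + d for d in (-4, -3, -2, -1, 1, 2, 3, 4)]
    out = []
    for v in grid:
        signs_ok = True
        changed = False
        prev_sign = np.sign(pos[k] - pos[k - 1])
        new_sign = np.sign(v - pos[k - 1])
        if new_sign == 0:
            continue
        if new_sign != prev_sign:
            changed = True
        if k + 1 < len(pos):
            prev2 = np.sign(pos[k + 1] - pos[k])
            new2 = np.sign(pos[k + 1] - v)
            if new2 == 0:
                continue
            if new2 != prev2:
                changed = True
        signs_ok = not changed
        if preserve and signs_ok:
            out.append(v)
        elif not preserve and changed:
            out.append(v)
    return out


_STRONG_GRID = (0, 2, 4, 6, 8, 12, 14)  # aligned to a 4-beat grid (unit = beat/2)
_WEAK_GRID = (0, 3, 5, 6, 9, 11, 14)  # syncopated variant of the same length


def make_rhythm_trial(task_id: str, ref_ioi_ms: float, delta_pct: float,
                      rng: np.random.Generator) -> dict:
    """Build one rhythm-domain trial descriptor.

    r1: two tone pairs; the target pair's gap is ``ref_ioi*(1+delta/100)``.
    r2: two five-tone sequences; the target lengthens the IOI between
    tones 3 and 4 by ``delta`` per cent. r3/r4: three seven-tone metrical
    sequences (XAB); the distorted one has a mid-sequence onset displaced
    by ``delta`` per cent of the beat.
    """
    if delta_pct < 0:
        raise ValueError("delta must be non-negative")
    tone = ToneSpec(500.0, 100.0)

    if task_id in ("r1", "r2"):
        if not 300.0 <= ref_ioi_ms <= 600.0:
            raise ValueError("reference IOI must lie in [300, 600] ms")
    if task_id == "r1":
        target = int(rng.integers(2))
        long_ioi = ref_ioi_ms * (1.0 + delta_pct / 100.0)
        iois = [ref_ioi_ms, ref_ioi_ms]
        iois[target] = long_ioi
        pairs = tuple(SequenceSpec((tone, tone), (0.0, ioi)) for ioi in iois)
        return {"task_id": "r1", "pairs": pairs, "answer": target,
                "undecidable": delta_pct == 0.0}
    if task_id == "r2":
        target = int(rng.integers(2))
        ref_onsets = tuple(ref_ioi_ms * i for i in range(5))
        extra = ref_ioi_ms * delta_pct / 100.0
        tgt_onsets = tuple(o + (extra if i >= 3 else 0.0) for i, o in enumerate(ref_onsets))
        seqs = [SequenceSpec((tone,) * 5, ref_onsets), SequenceSpec((tone,) * 5, ref_onsets)]
        seqs[target] = SequenceSpec((tone,) * 5, tgt_onsets)
        return {"task_id": "r2", "sequences": tuple(seqs), "answer": target,
                "undecidable": delta_pct == 0.0}
    if task_id in ("r3", "r4"):
        grid = _STRONG_GRID if task_id == "r3" else _WEAK_GRID
        unit = ref_ioi_ms / 2.0  # grid unit = half a beat
        ref_onsets = np.array(grid, dtype=float) * unit
        k = int(rng.integers(2, 6))  # displace a mid-sequence onset
        shift = ref_ioi_ms * delta_pct / 100.0 * float(rng.choice((-1, 1)))
        dist = ref_onsets.copy()
        dist[k] += shift
        lo = dist[k - 1] + tone.duration_ms / 2
        hi = dist[k + 1] - tone.duration_ms / 2
        dist[k] = float(np.clip(dist[k], lo, hi))
        target = int(rng.integers(2))  # which of A/B is distorted (X = reference)
        ab = [SequenceSpec((tone,) * 7, tuple(ref_onsets))] * 2
        ab[target] = SequenceSpec((tone,) * 7, tuple(dist))
        return {"task_id": task_id, "reference": SequenceSpec((tone,) * 7, tuple(ref_onsets)),
                "comparisons": tuple(ab), "answer": target,
                "undecidable": delta_pct == 0.0}
    raise ValueError(f"{task_id!r} is not a rhythm task")
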