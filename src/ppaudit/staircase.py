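"""Adaptive two-down one-up staircases, fixed-level runs and virtual observers.

The staircase makes the task harder (level divided by the current step
factor) after two consecutive correct responses and easier (level
multiplied by the step factor) after each error. Steps are multiplicative:
factor 2 until the second reversal, then sqrt(2). The threshold estimate is
the geometric mean of the last six reversal levels; this rule targets the
70.7%-correct point of the psychometric function (Levitt's rule for a
two-down one-up track).

Virtual observers respond through a logistic psychometric function in
log-difficulty,

    psi(x) = gamma + (1 - gamma - lambda) / (1 + exp(-beta (ln x - ln alpha)))

with guess rate gamma (0.5 for 2AFC, 1/3 for 3AFC), lapse rate lambda,
threshold alpha and slope beta. Same/different fixed-level tasks use a
high-threshold variant: the observer *detects* the change with probability
max(0, 2 F - 1) and responds "different" exactly when it detects (lapses
flip the response), so a non-perceiving observer scores at the 20/40
guessing level and a perfect observer scores 40/40.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from ._rng import child_rng
from .battery import TaskDefinition, get_task

__all__ = [
    "VirtualObserver",
    "StaircaseState",
    "StaircaseTrack",
    "observer_respond",
    "staircase_update",
    "estimate_threshold",
    "run_adaptive",
    "run_fixed",
    "convergence_level",
]

#: two-down one-up tracks converge where p(correct) = sqrt(1/2)
TWO_DOWN_ONE_UP_P = math.sqrt(0.5)

COARSE_STEP = 2.0
FINE_STEP = math.sqrt(2.0)
REVERSALS_FOR_FINE_STEP = 2
REVERSALS_FOR_THRESHOLD = 6


@dataclass(frozen=True)
class VirtualObserver:
    """A psychometric-function responder standing in for a human subject."""

    threshold: float  # alpha, in task difficulty units
    slope: float = 6.0  # beta, logistic slope in log-difficulty
    lapse: float = 0.02  # lambda
    guess: float = 0.5  # gamma

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if not 0.0 <= self.lapse <= 0.1:
            raise ValueError("lapse rate must lie in [0, 0.1]")

    def _F(self, delta: float) -> float:
        if delta <= 0.0:
            return 0.0 if self.slope > 0 else 0.5
        z = self.slope * (math.log(delta) - math.log(self.threshold))
        if z > 35:
            return 1.0
        if z < -35:
            return 0.0
        return 1.0 / (1.0 + math.exp(-z))

    def p_correct(self, delta: float) -> float:
        """Forced-choice probability correct; chance at delta = 0."""
        if delta <= 0.0:
            return self.guess
        return self.guess + (1.0 - self.guess - self.lapse) * self._F(delta)

    def p_detect(self, delta: float) -> float:
        """High-threshold detection probability for same/different tasks."""
        return max(0.0, 2.0 * self._F(delta) - 1.0)


def observer_respond(observer: VirtualObserver, delta: float,
                     rng: np.random.Generator, paradigm: str = "forced_choice",
                     is_different_trial: bool = True) -> bool:
    """Draw one response; returns True when the response is correct.

    ``paradigm`` "forced_choice" applies psi directly. "same_different"
    applies the high-threshold model: on 'different' trials the response
    is correct when the change is detected, on 'same' trials when no
    (lapse-induced) false 'different' occurs.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    if paradigm == "forced_choice":
        return bool(rng.random() < observer.p_correct(delta))
    if paradigm == "same_different":
        lapse_flip = rng.random() < observer.lapse
        if is_different_trial:
            detected = rng.random() < observer.p_detect(delta)
            return bool(detected != lapse_flip)
        return bool(not lapse_flip)
    raise ValueError(f"unknown paradigm {paradigm!r}")


@dataclass
class StaircaseState:
    """Mutable state of a running two-down one-up track."""

    level: float
    floor: float
    ceiling: float
    step_factor: float = COARSE_STEP
    consecutive_correct: int = 0
    trial_index: int = 0
    direction: str = "none"  # direction of the last level movement
    reversal_levels: list[float] = field(default_factory=list)

    def copy(self) -> "StaircaseState":
        s = dataclasses.replace(self)
        s.reversal_levels = list(self.reversal_levels)
        return s


def staircase_update(state: StaircaseState, correct: bool) -> StaircaseState:
    """Apply one response to the staircase; returns a new state.

    A reversal is recorded (at the pre-movement level) whenever the level
    movement direction flips. After the second reversal the step factor
    drops from 2 to sqrt(2). Levels are clipped to [floor, ceiling].
    """
    s = state.copy()
    s.trial_index += 1
    move = None
    if correct:
        s.consecutive_correct += 1
        if s.consecutive_correct >= 2:
            move = "down"
            s.consecutive_correct = 0
    else:
        move = "up"
        s.consecutive_correct = 0
    if move is not None:
        if s.direction != "none" and move != s.direction:
            s.reversal_levels.append(state.level)
            if len(s.reversal_levels) >= REVERSALS_FOR_FINE_STEP:
                s.step_factor = FINE_STEP
        factor = s.step_factor if move == "up" else 1.0 / s.step_factor
        s.level = float(np.clip(state.level * factor, s.floor, s.ceiling))
        s.direction = move
    return s


@dataclass
class StaircaseTrack:
    """Trial-by-trial record of one adaptive run plus its threshold."""

    task_id: str
    levels: list[float]
    responses: list[bool]
    reversal_flags: list[bool]
    reversal_levels: list[float]
    threshold: float
    converged: bool
    practice_trials: int = 0

    def __len__(self) -> int:
        return len(self.levels)


def estimate_threshold(track: StaircaseTrack | list[float],
                       n_reversals: int = REVERSALS_FOR_THRESHOLD) -> tuple[float, bool]:
    """Geometric mean of the last ``n_reversals`` reversal levels.

    Returns ``(nan, False)`` when the track produced fewer reversals than
    required; such tracks are flagged unconverged and excluded from group
    statistics downstream.
    """
    if isinstance(track, StaircaseTrack):
        if not track.levels:
            raise ValueError("empty track")
        revs = track.reversal_levels
    else:
        revs = list(track)
    if len(revs) < n_reversals:
        return float("nan"), False
    tail = np.asarray(revs[-n_reversals:], dtype=float)
    return float(np.exp(np.mean(np.log(tail)))), True


def _practice(task: TaskDefinition, observer: VirtualObserver,
              rng: np.random.Generator, max_trials: int = 200) -> tuple[float, int]:
    """Practice until five consecutive correct responses.

    Starts at the task's fixed start level (identical for all subjects);
    after each error the level is eased (doubled, up to the ceiling), so
    poor performers begin the test at an individually easier level.
    """
    level = task.start_level
    streak = 0
    for trial in range(max_trials):
        if observer_respond(observer, level, rng):
            streak += 1
            if streak >= 5:
                return level, trial + 1
        else:
            streak = 0
            level = float(min(level * 2.0, task.ceiling))
    return level, max_trials


def run_adaptive(task: TaskDefinition | str, observer: VirtualObserver,
                 seed: int | np.random.Generator) -> StaircaseTrack:
    """Simulate practice plus one 50-trial adaptive run.

    The observer's guess rate must match the task paradigm (0.5 for 2AFC,
    1/3 for 3AFC). Fully reproducible given the seed.
    """
    task = get_task(task) if isinstance(task, str) else task
    if not task.is_adaptive:
        raise ValueError(f"{task.task_id} is not an adaptive task")
    if not math.isclose(observer.guess, task.guess_rate, abs_tol=1e-9):
        raise ValueError(
            f"observer guess rate {observer.guess:.3f} incompatible with "
            f"{task.paradigm} (expected {task.guess_rate:.3f})"
        )
    rng = seed if isinstance(seed, np.random.Generator) else child_rng(seed)
    start_level, n_practice = _practice(task, observer, rng)
    state = StaircaseState(level=start_level, floor=task.floor, ceiling=task.ceiling)
    levels, responses, flags = [], [], []
    for _ in range(task.n_trials):
        levels.append(state.level)
        correct = observer_respond(observer, state.level, rng)
        responses.append(correct)
        n_rev = len(state.reversal_levels)
        state = staircase_update(state, correct)
        flags.append(len(state.reversal_levels) > n_rev)
    threshold, converged = estimate_threshold(state.reversal_levels)
    return StaircaseTrack(task.task_id, levels, responses, flags,
                          list(state.reversal_levels), threshold, converged,
                          practice_trials=n_practice)


def run_fixed(task: TaskDefinition | str, observer: VirtualObserver,
              seed: int | np.random.Generator) -> tuple[int, list[dict]]:
    """Simulate one fixed-difficulty same/different task (p3 or p4).

    40 trials: 20 of 20 reference sequences presented once as 'same' and
    once as 'different' (at the task's fixed difficulty), in shuffled
    order. Returns the integer score correct (0–40) and the trial log.
    """
    task = get_task(task) if isinstance(task, str) else task
    if task.paradigm != "fixed_same_different":
        raise ValueError(f"{task.task_id} is not a fixed same/different task")
    rng = seed if isinstance(seed, np.random.Generator) else child_rng(seed)
    trials = [(ref, cond) for ref in range(task.n_trials // 2) for cond in (True, False)]
    order = rng.permutation(len(trials))
    log, score = [], 0
    for idx in order:
        ref, is_diff = trials[idx]
        delta = task.fixed_delta if is_diff else 0.0
        correct = observer_respond(observer, delta, rng, paradigm="same_different",
                                   is_different_trial=is_diff)
        score += int(correct)
        log.append({"reference": ref, "different": is_diff, "correct": correct})
    return score, log


def convergence_level(observer: VirtualObserver) -> float:
    """Difficulty level a two-down one-up track converges to for this observer.

    Closed-form inverse of psi at p = sqrt(1/2): the level where
    F = (sqrt(.5) - gamma) / (1 - gamma - lambda).
    """
    f_target = (TWO_DOWN_ONE_UP_P - observer.guess) / (1.0 - observer.guess - observer.lapse)
    if not 0.0 < f_target < 1.0:
        raise ValueError("psychometric function never crosses the convergence point")
    logit = math.log(f_target / (1.0 - f_target))
    return observer.threshold * math.exp(logit / observer.slope)
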