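"""Synthetic cohorts with the statistical structure the analyses assume.

The generator emulates the study conditions: 28 controls and 18 patients
(8 SV, 6 NFV, 4 LV); log-normal thresholds for the five tasks whose
outcomes are log-transformed downstream (p1, r1, r2, m2, m3) and normal
thresholds elsewhere; binomial scores for the two fixed-difficulty pitch-
sequence tasks; a control-side correlation between fluid intelligence
(CPM) and the pitch-direction task (target r = -0.45, better cognition
lower threshold); a two-latent (semantic / repetition) structure over the
14-variable neuropsychological battery; and subtype deficit profiles in
control-SD units, worst for NFV on the sequence and rhythm tasks.

A ground-truth record accompanies every cohort for recovery tests; the
analysis stages never read it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_rng
from .battery import SCORE_TASKS, TASK_IDS, get_task
from .staircase import VirtualObserver, run_adaptive, run_fixed

__all__ = [
    "TaskModel",
    "CohortConfig",
    "NEURO_VARS",
    "generate_cohort",
    "generate_trial_level",
    "null_config",
]


@dataclass(frozen=True)
class TaskModel:
    """Control-population model of one task's underlying ability.

    For log-normal tasks ``loc`` is the geometric mean and ``scale`` the
    log-SD; for normal tasks they are the arithmetic mean and SD. Score
    tasks (p3/p4) model the underlying threshold, from which the score is
    drawn binomially.
    """

    loc: float
    scale: float
    log: bool


def _default_task_models() -> dict[str, TaskModel]:
    return {
        "p1": TaskModel(0.4, 0.80, True),    # semitones
        "p2": TaskModel(1.6, 0.40, False),   # semitones
        "p3": TaskModel(0.65, 0.25, True),   # underlying alpha, semitones
        "p4": TaskModel(0.70, 0.25, True),
        "r1": TaskModel(15.0, 0.70, True),   # % IOI
        "r2": TaskModel(12.0, 0.75, True),
        "r3": TaskModel(20.0, 5.0, False),   # % beat
        "r4": TaskModel(30.0, 7.0, False),
        "m1": TaskModel(0.03, 0.0075, False),  # FM depth fraction
        "m2": TaskModel(0.025, 0.85, True),
        "m3": TaskModel(0.12, 0.80, True),
        "m4": TaskModel(1.2, 0.30, False),   # cyc/oct
    }


#: the 14 neuropsychological variables with their two-factor loadings
#: (semantic/naming factor, repetition factor); noise variance fills the
#: remainder to unit variance
NEURO_VARS: dict[str, tuple[float, float]] = {
    "aat_written_word_matching": (0.85, 0.10),
    "boston_naming": (0.88, 0.08),
    "aat_auditory_word_matching": (0.85, 0.10),
    "ppt_pictures": (0.83, 0.12),
    "palpa_auditory_word_matching": (0.82, 0.05),
    "object_decision_hard": (0.78, 0.12),
    "palpa_assoc_semantic": (0.72, 0.30),
    "object_decision_easy": (0.72, 0.25),
    "aat_written_sentence_matching": (0.55, 0.45),
    "aat_auditory_sentence_matching": (0.58, 0.38),
    "palpa_pseudoword_repetition": (0.12, 0.85),
    "aat_repetition": (0.05, 0.82),
    "cpm": (0.15, 0.80),
    "palpa_word_repetition": (0.22, 0.75),
}


@dataclass
class CohortConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_controls: int = 28
    subgroups: dict[str, int] = field(
        default_factory=lambda: {"SV": 8, "NFV": 6, "LV": 4})
    task_models: dict[str, TaskModel] = field(default_factory=_default_task_models)
    #: per-subtype, per-task deficit shift in control SD units (positive = worse)
    deficit_profiles: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "SV": {"r3": 1.3},
        "NFV": {"p3": 3.0, "p4": 1.0, "r2": 1.2, "r3": 1.2, "r4": 2.6, "m4": 1.2},
        "LV": {},
    })
    #: per-subtype shifts of the (semantic, repetition) latents, SD units
    latent_shifts: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "SV": (-2.5, -0.5), "NFV": (-0.5, -2.0), "LV": (-0.5, -1.0)})
    #: target control-side correlation between CPM and the p2 threshold
    cpm_p2_corr: float = -0.45
    #: coupling of the repetition latent into the p3/p4 underlying threshold
    sequence_f2_coupling: float = 0.3
    observer_slope: float = 6.0  # adaptive-task psychometric slope
    observer_slope_fixed: float = 3.0  # fixed same/different tasks
    observer_lapse: float = 0.02
    age_mean_controls: float = 62.0
    age_mean_patients: float = 65.0
    age_sd: float = 8.0

    def __post_init__(self) -> None:
        if self.n_controls < 0 or any(n < 0 for n in self.subgroups.values()):
            raise ValueError("group sizes must be non-negative")
        if not -1.0 < self.cpm_p2_corr < 1.0:
            raise ValueError("correlation target must lie in (-1, 1)")
        for prof in self.deficit_profiles.values():
            if any(not np.isfinite(s) for s in prof.values()):
                raise ValueError("deficit shifts must be finite")
        a2 = NEURO_VARS["cpm"][1]
        if abs(self.cpm_p2_corr) >= a2:
            raise ValueError(
                f"correlation target {self.cpm_p2_corr} infeasible: CPM loads "
                f"{a2} on the repetition latent, capping |r| below that")


def null_config() -> CohortConfig:
    """Study-size cohort with no implanted deficits (null pipeline runs)."""
    cfg = CohortConfig()
    cfg.deficit_profiles = {"SV": {}, "NFV": {}, "LV": {}}
    cfg.latent_shifts = {"SV": (0.0, 0.0), "NFV": (0.0, 0.0), "LV": (0.0, 0.0)}
    return cfg


def _binomial_score(alpha: np.ndarray, slope: float, lapse: float,
                    delta: float, rng: np.random.Generator) -> np.ndarray:
    """Score /40 from the high-threshold same/different observer model."""
    F = 1.0 / (1.0 + (alpha / delta) ** slope)
    pd_ = np.maximum(0.0, 2.0 * F - 1.0)
    p_diff = pd_ * (1.0 - lapse) + (1.0 - pd_) * lapse
    return (rng.binomial(20, 1.0 - lapse, size=len(alpha))
            + rng.binomial(20, p_diff)).astype(float)


def generate_cohort(config: CohortConfig | None = None, seed: int = 0
                    ) -> tuple[pd.DataFrame, dict]:
    """Generate one cohort table plus its ground-truth record.

    Outcome columns hold the underlying ability directly (exact for
    adaptive tasks, a binomial score draw for p3/p4); use
    `generate_trial_level` to replace them with staircase measurements.
    """
    cfg = config if config is not None else CohortConfig()
    groups = (["control"] * cfg.n_controls
              + [g for g, n in cfg.subgroups.items() for _ in range(n)])
    n = len(groups)
    ids = []
    counters: dict[str, int] = {}
    for g in groups:
        counters[g] = counters.get(g, 0) + 1
        prefix = "C" if g == "control" else g
        ids.append(f"{prefix}{counters[g]:02d}")

    rng_lat = child_rng(seed, 1)
    rng_task = child_rng(seed, 2)
    rng_demo = child_rng(seed, 3)
    rng_neuro = child_rng(seed, 4)
    rng_score = child_rng(seed, 5)

    f1 = rng_lat.normal(size=n)
    f2 = rng_lat.normal(size=n)
    for i, g in enumerate(groups):
        if g != "control":
            s1, s2 = cfg.latent_shifts.get(g, (0.0, 0.0))
            f1[i] += s1
            f2[i] += s2

    a2_cpm = NEURO_VARS["cpm"][1]
    c_p2 = cfg.cpm_p2_corr / a2_cpm  # coupling of f2 into the p2 threshold
    c_seq = cfg.sequence_f2_coupling

    alphas = {}
    for task in TASK_IDS:
        tm = cfg.task_models[task]
        eps = rng_task.normal(size=n)
        if task == "p2":
            z = c_p2 * f2 + np.sqrt(1.0 - c_p2**2) * eps
        elif task in SCORE_TASKS:
            z = c_seq * (-f2) + np.sqrt(max(0.0, 1.0 - c_seq**2)) * eps
        else:
            z = eps
        for i, g in enumerate(groups):
            if g != "control":
                z[i] += cfg.deficit_profiles.get(g, {}).get(task, 0.0)
        if tm.log:
            alphas[task] = np.exp(np.log(tm.loc) + tm.scale * z)
        else:
            floor = get_task(task).floor
            alphas[task] = np.maximum(tm.loc + tm.scale * z, floor)
    alpha_df = pd.DataFrame(alphas, index=ids)

    outcomes = {}
    for task in TASK_IDS:
        if task in SCORE_TASKS:
            outcomes[task] = _binomial_score(
                alpha_df[task].to_numpy(), cfg.observer_slope_fixed,
                cfg.observer_lapse, get_task(task).fixed_delta, rng_score)
        else:
            outcomes[task] = alpha_df[task].to_numpy().copy()

    is_ctrl = np.array([g == "control" for g in groups])
    age = np.where(is_ctrl,
                   rng_demo.normal(cfg.age_mean_controls, cfg.age_sd, n),
                   rng_demo.normal(cfg.age_mean_patients, cfg.age_sd, n))
    age = np.clip(np.round(age), 45, 80)
    duration = np.round(np.exp(rng_demo.normal(np.log(2.5), 0.6, n)) * 2) / 2
    duration = np.where(is_ctrl, np.nan, np.clip(duration, 0.5, 8.0))
    hearing = np.clip(np.round(rng_demo.normal(18.0, 6.0, n)), 5, 30)
    digit_span = np.clip(np.round(5.5 + 1.1 * f2 + 0.5 * rng_demo.normal(size=n)), 2, 9)

    neuro = {}
    for var, (a1, a2) in NEURO_VARS.items():
        noise = np.sqrt(max(0.0, 1.0 - a1**2 - a2**2))
        val = a1 * f1 + a2 * f2 + noise * rng_neuro.normal(size=n)
        if var == "cpm":
            neuro[var] = np.clip(np.round(29.0 + 3.5 * val), 0, 36)
        else:
            neuro[var] = np.round(50.0 + 10.0 * val, 1)

    table = pd.DataFrame({
        "subject_id": ids, "group": groups, "age": age,
        "symptom_duration_years": duration, "hearing_level_db": hearing,
        "digit_span": digit_span, **neuro, **outcomes,
    })
    truth = {
        "alpha": alpha_df,
        "f_semantic": pd.Series(f1, index=ids),
        "f_repetition": pd.Series(f2, index=ids),
        "config": asdict(cfg),
        "seed": seed,
    }
    return table, truth


def generate_trial_level(cohort: pd.DataFrame, truth: dict, seed: int = 0,
                         config: CohortConfig | None = None
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every subject's staircase/fixed runs from true thresholds.

    Each subject becomes a `VirtualObserver` with alpha equal to the true
    underlying threshold. Returns (measured, tracks): ``measured`` has one
    row per subject with the 12 estimated outcomes (NaN for unconverged
    staircases), ``tracks`` is the tidy trial-level log.
    """
    cfg = config if config is not None else CohortConfig()
    if config is None and "config" in truth:
        # prefer the generating configuration for observer parameters
        gen = truth["config"]
        cfg.observer_slope = gen.get("observer_slope", cfg.observer_slope)
        cfg.observer_slope_fixed = gen.get("observer_slope_fixed", cfg.observer_slope_fixed)
        cfg.observer_lapse = gen.get("observer_lapse", cfg.observer_lapse)
    alpha_df: pd.DataFrame = truth["alpha"]
    rows = []
    measured: dict[str, list[float]] = {t: [] for t in TASK_IDS}
    for si, sid in enumerate(cohort["subject_id"]):
        for ti, task_id in enumerate(TASK_IDS):
            task = get_task(task_id)
            alpha = float(alpha_df.loc[sid, task_id])
            slope = cfg.observer_slope_fixed if task_id in SCORE_TASKS else cfg.observer_slope
            obs = VirtualObserver(threshold=alpha, slope=slope,
                                  lapse=cfg.observer_lapse, guess=task.guess_rate)
            rng = child_rng(seed, 10, si, ti)
            if task.is_adaptive:
                track = run_adaptive(task, obs, rng)
                measured[task_id].append(track.threshold if track.converged else np.nan)
                for tr, (lev, resp, rev) in enumerate(
                        zip(track.levels, track.responses, track.reversal_flags)):
                    rows.append((sid, task_id, tr + 1, lev, resp, rev))
            else:
                score, log = run_fixed(task, obs, rng)
                measured[task_id].append(float(score))
                for tr, entry in enumerate(log):
                    rows.append((sid, task_id, tr + 1, task.fixed_delta
                                 if entry["different"] else 0.0,
                                 entry["correct"], False))
    measured_df = pd.DataFrame({"subject_id": list(cohort["subject_id"]), **measured})
    tracks = pd.DataFrame(rows, columns=["subject", "task", "trial", "level",
                                         "correct", "reversal_flag"])
    return measured_df, tracks
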