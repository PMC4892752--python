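"""Single-case deficit detection against a small control sample.

The modified t-test treats the control mean and SD as sample estimates
rather than population parameters:

    t = (x* - xbar) / (s * sqrt((n + 1) / n)),   df = n - 1

with a one-tailed p in the task's deficit direction (thresholds: higher is
worse; scores correct: lower is worse). Exact p-values are mapped to
normalized Z-scores through the standard normal quantile, z = Phi^-1(1-p),
signed so that deficits are positive; the per-battery significance
criterion is z > Phi^-1(1 - 0.05/12) = 2.64 (one-tailed 0.05, Bonferroni
over the 12 tasks).

The covariate-adjusted variant compares the patient with the control
regression on covariates (age, fluid intelligence):

    t = (y* - yhat*) / (s_e * sqrt(1 + h*)),     df = n - k - 1

where yhat* is the patient's predicted score from the control fit, s_e the
residual SD and h* = x0'(X0'X0)^-1 x0 the patient's leverage with an
intercept-augmented design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .battery import SCORE_TASKS, TASK_IDS

__all__ = [
    "ControlNorm",
    "SingleCaseResult",
    "DEFICIT_DIRECTION",
    "crawford_t",
    "p_to_z",
    "z_threshold",
    "select_covariates",
    "adjusted_singlecase",
    "single_case_table",
    "CrawfordDeficitModel",
]

#: per-task deficit direction: True when a higher outcome means worse
#: performance (thresholds), False for scores correct (p3, p4)
DEFICIT_DIRECTION: dict[str, bool] = {t: t not in SCORE_TASKS for t in TASK_IDS}

N_BATTERY_TESTS = 12


@dataclass(frozen=True)
class ControlNorm:
    """Control-sample summary for one task."""

    task_id: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least two controls")
        if not self.sd > 0:
            raise ValueError("control SD must be positive")


@dataclass(frozen=True)
class SingleCaseResult:
    patient_id: str
    task_id: str
    t: float
    df: int
    p_one_tailed: float
    z: float
    impaired_uncorrected: bool
    impaired_bonferroni: bool
    adjusted: bool


def crawford_t(x_star, mean: float, sd: float, n: int,
               higher_worse: bool = True):
    """Modified t-test of one (or an array of) case(s) against control norms.

    Returns ``(t, df, p_one_tailed)``; ``t`` carries the raw sign of
    ``x* - mean`` while ``p`` is the upper-tail probability in the deficit
    direction, so a case better than controls yields p > 0.5.
    """
    if n < 2:
        raise ValueError("need at least two controls")
    if not sd > 0:
        raise ValueError("control SD must be positive")
    x = np.asarray(x_star, dtype=float)
    t = (x - mean) / (sd * np.sqrt((n + 1.0) / n))
    df = n - 1
    t_deficit = t if higher_worse else -t
    p = stats.t.sf(t_deficit, df)
    if x.ndim == 0:
        return float(t), df, float(p)
    return t, df, p


def p_to_z(p_one_tailed):
    """Map one-tailed deficit p-values to normalized Z (deficit positive)."""
    p = np.asarray(p_one_tailed, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("p must lie strictly between 0 and 1")
    z = stats.norm.isf(p)
    return float(z) if p.ndim == 0 else z


def z_threshold(alpha: float = 0.05, n_tests: int = N_BATTERY_TESTS) -> float:
    """Bonferroni-corrected one-tailed Z criterion, Phi^-1(1 - alpha/n)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return float(stats.norm.isf(alpha / n_tests))


def select_covariates(controls: pd.DataFrame, candidates: list[str],
                      outcomes: list[str] | None = None,
                      alpha: float = 0.05) -> list[str]:
    """Screen candidate covariates on the control sample.

    Fits, per task, ``outcome ~ candidates`` (OLS with intercept) in
    controls and returns the candidates whose coefficient is significant
    (two-tailed p < alpha) for at least one task. A candidate selected for
    any task is used for all twelve. Constant candidates are dropped with
    a warning; collinear candidate sets raise.
    """
    import statsmodels.api as sm

    outcomes = list(outcomes) if outcomes is not None else list(TASK_IDS)
    usable = []
    for c in candidates:
        if c not in controls.columns:
            raise KeyError(f"candidate covariate {c!r} not in table")
        if np.nanstd(controls[c].to_numpy(dtype=float)) == 0.0:
            warnings.warn(f"covariate {c!r} is constant across controls; excluded")
        else:
            usable.append(c)
    if not usable:
        return []
    X = controls[usable].to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X])) < len(usable) + 1:
        cond = np.linalg.cond(np.column_stack([np.ones(len(X)), X]))
        raise ValueError(f"collinear covariates (condition number {cond:.3g})")
    selected: set[str] = set()
    for task in outcomes:
        y = controls[task].to_numpy(dtype=float)
        ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
        fit = sm.OLS(y[ok], sm.add_constant(X[ok])).fit()
        for j, c in enumerate(usable, start=1):
            if fit.pvalues[j] < alpha:
                selected.add(c)
    return [c for c in usable if c in selected]


def adjusted_singlecase(y_star: float, x_star, controls_y, controls_X,
                        higher_worse: bool = True):
    """Covariate-adjusted single-case comparison (regression norms).

    Returns ``(t, df, p_one_tailed)`` with df = n - k - 1.
    """
    y = np.asarray(controls_y, dtype=float)
    X = np.atleast_2d(np.asarray(controls_X, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    x0 = np.concatenate([[1.0], np.atleast_1d(np.asarray(x_star, dtype=float))])
    if np.any(~np.isfinite(x0)):
        raise ValueError("patient covariate values missing")
    n, k = X.shape
    if n <= k + 2:
        raise ValueError("too few controls for the number of covariates")
    X0 = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(X0) < k + 1:
        raise ValueError("rank-deficient control design matrix")
    beta, *_ = np.linalg.lstsq(X0, y, rcond=None)
    resid = y - X0 @ beta
    df = n - k - 1
    s_e = np.sqrt(resid @ resid / df)
    h_star = float(x0 @ np.linalg.solve(X0.T @ X0, x0))
    t = float((y_star - x0 @ beta) / (s_e * np.sqrt(1.0 + h_star)))
    t_deficit = t if higher_worse else -t
    p = float(stats.t.sf(t_deficit, df))
    return t, df, p


def _result(patient_id: str, task_id: str, t: float, df: int, p: float,
            adjusted: bool, alpha: float = 0.05) -> SingleCaseResult:
    z = p_to_z(min(max(p, 1e-300), 1 - 1e-16))
    return SingleCaseResult(
        patient_id=patient_id, task_id=task_id, t=t, df=df, p_one_tailed=p, z=z,
        impaired_uncorrected=p < alpha,
        impaired_bonferroni=p < alpha / N_BATTERY_TESTS,
        adjusted=adjusted,
    )


def single_case_table(cohort: pd.DataFrame, tasks: list[str] | None = None,
                      covariates: list[str] | None = None,
                      group_col: str = "group", control_label: str = "control",
                      id_col: str = "subject_id") -> pd.DataFrame:
    """Run the modified t-test (and, with covariates, the adjusted variant)
    for every patient on every task; returns a tidy long table.

    Missing patient scores propagate as missing rows flagged unconverged;
    the Bonferroni correction stays at n = 12 regardless.
    """
    tasks = list(tasks) if tasks is not None else list(TASK_IDS)
    ctrl = cohort[cohort[group_col] == control_label]
    pats = cohort[cohort[group_col] != control_label]
    rows = []
    for task in tasks:
        higher_worse = DEFICIT_DIRECTION.get(task, True)
        yc = ctrl[task].to_numpy(dtype=float)
        yc = yc[np.isfinite(yc)]
        norm = ControlNorm(task, len(yc), float(np.mean(yc)), float(np.std(yc, ddof=1)))
        if covariates:
            mask = np.all(np.isfinite(ctrl[covariates].to_numpy(dtype=float)), axis=1)
            mask &= np.isfinite(ctrl[task].to_numpy(dtype=float))
            Xc = ctrl.loc[mask, covariates].to_numpy(dtype=float)
            yc_adj = ctrl.loc[mask, task].to_numpy(dtype=float)
        for _, pat in pats.iterrows():
            y_star = float(pat[task])
            if not np.isfinite(y_star):
                continue  # task not performed: propagate as missing
            t, df, p = crawford_t(y_star, norm.mean, norm.sd, norm.n, higher_worse)
            rows.append(_result(str(pat[id_col]), task, t, df, p, adjusted=False))
            if covariates:
                x_star = pat[covariates].to_numpy(dtype=float)
                t2, df2, p2 = adjusted_singlecase(y_star, x_star, yc_adj, Xc, higher_worse)
                rows.append(_result(str(pat[id_col]), task, t2, df2, p2, adjusted=True))
    out = pd.DataFrame([r.__dict__ for r in rows])
    return out


class CrawfordDeficitModel(BaseEstimator):
    """Sklearn-style wrapper: fit on control outcomes, score patients.

    Parameters
    ----------
    alpha : family-wise significance level (default 0.05).
    n_tests : Bonferroni family size (default 12, the battery size).
    directions : optional mapping column -> higher_is_worse; defaults to the
        battery registry for known task ids and higher-is-worse otherwise.

    Attributes (after fit)
    ----------------------
    norms_ : dict of column -> ControlNorm
    columns_ : fitted outcome columns
    z_criterion_ : Bonferroni Z threshold
    """

    def __init__(self, alpha: float = 0.05, n_tests: int = N_BATTERY_TESTS,
                 directions: dict[str, bool] | None = None):
        self.alpha = alpha
        self.n_tests = n_tests
        self.directions = directions

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        self.columns_ = list(X.columns)
        self.norms_ = {}
        for c in self.columns_:
            v = X[c].to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            self.norms_[c] = ControlNorm(str(c), len(v), float(np.mean(v)),
                                         float(np.std(v, ddof=1)))
        self.z_criterion_ = z_threshold(self.alpha, self.n_tests)
        return self

    def _direction(self, c) -> bool:
        if self.directions is not None and c in self.directions:
            return self.directions[c]
        return DEFICIT_DIRECTION.get(c, True)

    def z_scores(self, X: pd.DataFrame) -> pd.DataFrame:
        """Deficit-positive Z score per case per column."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "norms_")
        X = pd.DataFrame(X)
        out = {}
        for c in self.columns_:
            norm = self.norms_[c]
            _, _, p = crawford_t(X[c].to_numpy(dtype=float), norm.mean, norm.sd,
                                 norm.n, self._direction(c))
            out[c] = p_to_z(np.clip(p, 1e-300, 1 - 1e-16))
        return pd.DataFrame(out, index=X.index)

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        """Boolean impairment flags at the Bonferroni-corrected criterion."""
        return self.z_scores(X) > self.z_criterion_
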