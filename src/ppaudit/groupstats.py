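"""Cohort-level statistics: normality screening, log-transform policy,
group and subtype comparisons, and correlation families.

The screening/transform policy mirrors common practice with threshold
data: every task outcome is tested for composite normality (Lilliefors)
separately in controls and in patients, and log-transformed for both
groups whenever either deviates. Group comparisons are one-sided
independent-samples t-tests (patients worse), Bonferroni-corrected over
the 12 tasks; subtype comparisons use Kruskal–Wallis with post hoc
Tukey–Kramer contrasts on rank means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors as _sm_lilliefors

from .battery import TASK_IDS
from .singlecase import DEFICIT_DIRECTION

__all__ = [
    "GroupComparisonResult",
    "lilliefors",
    "apply_transform_policy",
    "group_compare",
    "kruskal_wallis",
    "tukey_kramer_ranks",
    "corr_tests",
]

N_BATTERY_TESTS = 12


@dataclass(frozen=True)
class GroupComparisonResult:
    task_id: str
    transform_applied: bool
    statistic: float
    df: float
    p: float
    significant_bonferroni: bool
    direction_patients_worse: bool


def lilliefors(x, alpha_hint: float = 0.05) -> tuple[float, float]:
    """Lilliefors composite-normality test (KS with estimated mean/SD).

    Returns ``(D, p)``. Requires n >= 5; a constant sample raises.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 5:
        raise ValueError("need at least five observations")
    if np.std(x) == 0.0:
        raise ValueError("constant sample has no defined normality test")
    d, p = _sm_lilliefors(x, dist="norm", pvalmethod="table")
    return float(d), float(p)


def apply_transform_policy(cohort: pd.DataFrame, tasks: list[str] | None = None,
                           alpha: float = 0.05, group_col: str = "group",
                           control_label: str = "control",
                           already_logged: list[str] | None = None
                           ) -> tuple[pd.DataFrame, list[str]]:
    """Log-transform every task that deviates from normality in controls
    OR in patients; the transform is applied to both groups.

    Returns the transformed table and the list of logged tasks. Tasks in
    ``already_logged`` are skipped (idempotence). A non-positive value in
    a task selected for logging raises.
    """
    tasks = list(tasks) if tasks is not None else list(TASK_IDS)
    already = set(already_logged or [])
    out = cohort.copy()
    logged = []
    is_ctrl = cohort[group_col] == control_label
    for task in tasks:
        if task in already:
            continue
        v = cohort[task].to_numpy(dtype=float)
        pc = lilliefors(v[is_ctrl.to_numpy()])[1]
        pp = lilliefors(v[~is_ctrl.to_numpy()])[1]
        if pc < alpha or pp < alpha:
            vals = v[np.isfinite(v)]
            if np.any(vals <= 0):
                raise ValueError(f"task {task!r} selected for log transform "
                                 "but contains non-positive values")
            out[task] = np.log(cohort[task].to_numpy(dtype=float))
            logged.append(task)
    return out, logged


def group_compare(cohort: pd.DataFrame, tasks: list[str] | None = None,
                  alpha: float = 0.05, group_col: str = "group",
                  control_label: str = "control", equal_var: bool = True,
                  transformed: list[str] | None = None
                  ) -> list[GroupComparisonResult]:
    """One-sided independent-samples t-test per task, patients-worse
    alternative, Bonferroni flag at alpha / 12."""
    tasks = list(tasks) if tasks is not None else list(TASK_IDS)
    transformed = set(transformed or [])
    is_ctrl = cohort[group_col] == control_label
    results = []
    for task in tasks:
        if task not in cohort.columns:
            raise KeyError(f"missing task column {task!r}")
        c = cohort.loc[is_ctrl, task].dropna().to_numpy(dtype=float)
        p_ = cohort.loc[~is_ctrl, task].dropna().to_numpy(dtype=float)
        if len(c) < 2 or len(p_) < 2:
            raise ValueError("need at least two subjects per group")
        higher_worse = DEFICIT_DIRECTION.get(task, True)
        alternative = "greater" if higher_worse else "less"
        res = stats.ttest_ind(p_, c, equal_var=equal_var, alternative=alternative)
        df = len(c) + len(p_) - 2 if equal_var else float(res.df)
        pat_worse = (np.mean(p_) > np.mean(c)) == higher_worse
        results.append(GroupComparisonResult(
            task_id=task, transform_applied=task in transformed,
            statistic=float(res.statistic), df=float(df), p=float(res.pvalue),
            significant_bonferroni=bool(res.pvalue < alpha / N_BATTERY_TESTS),
            direction_patients_worse=bool(pat_worse)))
    return results


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, int, float]:
    """Tie-corrected Kruskal–Wallis H with chi-square upper-tail p."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[np.isfinite(g)] for g in groups]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need at least two non-empty groups")
    if sum(len(g) for g in groups) < 5:
        raise ValueError("too few observations overall")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        raise ValueError("all values tied; rank test undefined")
    h, p = stats.kruskal(*groups)
    return float(h), len(groups) - 1, float(p)


def kw_tail_p(h: float, df: int) -> float:
    """Chi-square upper-tail p for a Kruskal–Wallis H statistic."""
    return float(stats.chi2.sf(h, df))


def tukey_kramer_ranks(groups: dict[str, np.ndarray] | list[np.ndarray],
                       alpha: float = 0.05) -> list[dict]:
    """Tukey–Kramer pairwise contrasts on pooled rank means.

    Follows the usual post-hoc-after-Kruskal–Wallis construction: pooled
    midranks, tie-corrected rank variance N(N+1)/12, unequal-n standard
    errors and the studentized-range critical value (infinite df).
    Returns one record per pair with the rank-mean difference and flag.
    """
    if isinstance(groups, dict):
        names = list(groups)
        samples = [np.asarray(groups[k], dtype=float) for k in names]
    else:
        names = [str(i) for i in range(len(groups))]
        samples = [np.asarray(g, dtype=float) for g in groups]
    samples = [s[np.isfinite(s)] for s in samples]
    k = len(samples)
    if k < 2:
        raise ValueError("need at least two groups")
    pooled = np.concatenate(samples)
    n_tot = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction to the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n_tot**3 - n_tot)
    var = tie * n_tot * (n_tot + 1.0) / 12.0
    mean_ranks, sizes, idx = [], [], 0
    for s in samples:
        mean_ranks.append(float(np.mean(ranks[idx: idx + len(s)])))
        sizes.append(len(s))
        idx += len(s)
    q_crit = stats.studentized_range.ppf(1.0 - alpha, k, 1e7)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            diff = mean_ranks[i] - mean_ranks[j]
            stat = abs(diff) / (se / np.sqrt(2.0))
            out.append({
                "pair": (names[i], names[j]),
                "rank_mean_diff": diff,
                "q": float(stat),
                "q_critical": float(q_crit),
                "significant": bool(stat > q_crit),
            })
    return out


def corr_tests(df: pd.DataFrame, x: str, y_set: list[str],
               method: str = "pearson", sided: str = "two",
               n_tests: int | None = None) -> pd.DataFrame:
    """Correlate one column with a set of outcomes, Bonferroni-corrected.

    ``sided`` 'two' reports two-tailed p; 'one' halves the p of the
    observed direction. Corrected p = min(1, m * p). Pairs with fewer
    than four complete observations or zero variance raise.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    m = n_tests if n_tests is not None else len(y_set)
    xv = df[x].to_numpy(dtype=float)
    rows = []
    for y in y_set:
        yv = df[y].to_numpy(dtype=float)
        ok = np.isfinite(xv) & np.isfinite(yv)
        if ok.sum() < 4:
            raise ValueError(f"fewer than four paired observations for {y!r}")
        a, b = xv[ok], yv[ok]
        if np.std(a) == 0 or np.std(b) == 0:
            raise ValueError(f"zero variance in correlation pair ({x!r}, {y!r})")
        if method == "pearson":
            r, p = stats.pearsonr(a, b)
        else:
            r, p = stats.spearmanr(a, b)
        if sided == "one":
            p = p / 2.0
        p_corr = min(1.0, m * p)
        rows.append({"x": x, "y": y, "n": int(ok.sum()), "method": method,
                     "r": float(r), "p": float(p), "p_corrected": float(p_corr),
                     "significant_corrected": bool(p_corr < 0.05)})
    return pd.DataFrame(rows)
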