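"""End-to-end analysis driver: cohort -> battery simulation -> statistics.

Mirrors the study's analysis order: transform policy, group comparison,
subtype Kruskal–Wallis with post hoc contrasts, single-case modified
t-tests (raw and covariate-adjusted), pairwise subtype SVM, factor
analysis of the neuropsychological battery, and the correlation families
(factor scores, symptom duration, hearing level, digit span).

``headline_findings`` extracts the cohort-level Bonferroni-corrected
claims (the group patient-vs-control deficits); subtype Kruskal–Wallis
tests and the SVM permutation p are reported at uncorrected thresholds,
as in the study, and per-patient single-case flags form per-patient
families — neither enters the corrected headline set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .battery import TASK_IDS
from .classify import classify_all_pairs
from .cohort import NEURO_VARS, CohortConfig, generate_cohort, generate_trial_level
from .factors import factor_psychoacoustic_corr, fit_factors
from .groupstats import (apply_transform_policy, corr_tests, group_compare,
                         kruskal_wallis, tukey_kramer_ranks)
from .singlecase import select_covariates, single_case_table, z_threshold

__all__ = ["end_to_end", "analyze_cohort", "headline_findings",
           "REPORT_SECTIONS", "validate_report"]

REPORT_SECTIONS = ("cohort", "transform", "group", "subtype", "single_case",
                   "svm", "factors", "correlations", "headline")


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.bool_):
        return bool(x)
    if isinstance(x, pd.DataFrame):
        return _jsonable(x.to_dict(orient="records"))
    if isinstance(x, pd.Series):
        return _jsonable(x.to_dict())
    if isinstance(x, np.ndarray):
        return _jsonable(x.tolist())
    if isinstance(x, float) and not np.isfinite(x):
        return None
    return x


def analyze_cohort(cohort: pd.DataFrame, seed: int = 0,
                   svm_permutations: int = 1000, adjust: bool = True,
                   alpha: float = 0.05) -> dict:
    """Run the full statistical pipeline on a cohort table."""
    report: dict = {}
    neuro_cols = [c for c in NEURO_VARS if c in cohort.columns]
    task_cols = [t for t in TASK_IDS if t in cohort.columns]

    transformed, logged = apply_transform_policy(cohort, tasks=task_cols, alpha=alpha)
    report["transform"] = {"logged_tasks": logged, "alpha": alpha}

    group_results = group_compare(transformed, tasks=task_cols, transformed=logged)
    report["group"] = [r.__dict__ for r in group_results]

    patients = transformed[transformed["group"] != "control"]
    subtype: dict = {}
    subtypes = sorted(patients["group"].unique())
    for task in task_cols:
        try:
            groups = {g: patients.loc[patients["group"] == g, task].dropna().to_numpy()
                      for g in subtypes}
            h, df, p = kruskal_wallis(list(groups.values()))
            entry = {"H": h, "df": df, "p": p, "significant": p < alpha}
            if p < alpha:
                entry["posthoc"] = tukey_kramer_ranks(groups, alpha=alpha)
            subtype[task] = entry
        except ValueError as exc:
            subtype[task] = {"error": f"subtype stage skipped: {exc}"}
    report["subtype"] = subtype

    controls = transformed[transformed["group"] == "control"]
    covariates: list[str] = []
    if adjust:
        covariates = select_covariates(controls, ["age", "cpm"], outcomes=task_cols)
    sc = single_case_table(transformed, tasks=task_cols,
                           covariates=covariates or None)
    zc = z_threshold(alpha, 12)
    raw = sc[~sc["adjusted"]]
    mean_z = raw.groupby(sc["patient_id"].map(
        dict(zip(transformed["subject_id"], transformed["group"]))))["z"].mean()
    counts = (raw[raw["impaired_bonferroni"]]
              .groupby("task_id")["patient_id"].count().to_dict())
    report["single_case"] = {
        "covariates": covariates,
        "z_criterion": zc,
        "results": sc,
        "mean_z_by_subtype": mean_z.to_dict(),
        "n_impaired_bonferroni_by_task": counts,
    }

    svm_patients = patients.copy()
    # unconverged staircases leave missing outcomes; mean-impute within the
    # patient sample so the classifier keeps every case
    svm_patients[task_cols] = svm_patients[task_cols].fillna(
        svm_patients[task_cols].mean())
    svm = classify_all_pairs(svm_patients, task_cols, seed=seed,
                             n_perm=svm_permutations) if len(subtypes) >= 2 else []
    report["svm"] = [
        {"pair": list(r.pair), "accuracy": r.accuracy, "p_perm": r.p_perm,
         "n_misclassified": r.n_misclassified, "n": r.n,
         "feature_weights": r.feature_weights, "feature_ranking": r.feature_ranking}
        for r in svm]

    solution = fit_factors(transformed[neuro_cols]) if neuro_cols else None
    if solution is not None:
        pat_scores = solution.factor_scores.loc[patients.index]
        fcorr = factor_psychoacoustic_corr(pat_scores, patients, task_cols)
        report["factors"] = {
            "eigenvalues": solution.eigenvalues[: solution.factor_scores.shape[1]],
            "variance_explained": solution.variance_explained,
            "total_variance_explained": float(np.sum(solution.variance_explained)),
            "loadings": solution.loadings,
            "task_correlations": fcorr,
        }
    else:
        report["factors"] = {"error": "no neuropsychological columns present"}

    correlations = {}
    for x, method, col in (("symptom_duration_years", "pearson", "duration"),
                           ("hearing_level_db", "pearson", "hearing"),
                           ("digit_span", "spearman", "digit_span")):
        if x in patients.columns and patients[x].notna().sum() >= 4:
            correlations[col] = corr_tests(patients, x, task_cols, method=method,
                                           sided="two", n_tests=12)
        else:
            correlations[col] = {"error": f"{x} unavailable"}
    report["correlations"] = correlations

    report["headline"] = {
        "group_deficit_tasks": [r.task_id for r in group_results
                                if r.significant_bonferroni
                                and r.direction_patients_worse],
    }
    return report


def end_to_end(config: CohortConfig | None = None, seed: int = 0,
               simulate_trials: bool = True, svm_permutations: int = 1000,
               adjust: bool = True) -> dict:
    """Generate a cohort, optionally measure it trial-by-trial through the
    adaptive engine, and run the full analysis; returns the report dict."""
    cohort, truth = generate_cohort(config, seed)
    report: dict = {"seed": seed}
    if simulate_trials:
        measured, tracks = generate_trial_level(cohort, truth, seed=seed)
        cohort = cohort.copy()
        for t in TASK_IDS:
            cohort[t] = measured[t].to_numpy()
        report["n_unconverged"] = int(measured[list(TASK_IDS)].isna().sum().sum())
    report["cohort"] = {
        "n_controls": int((cohort["group"] == "control").sum()),
        "subgroups": cohort.loc[cohort["group"] != "control", "group"]
        .value_counts().to_dict(),
        "simulate_trials": simulate_trials,
    }
    report.update(analyze_cohort(cohort, seed=seed,
                                 svm_permutations=svm_permutations, adjust=adjust))
    return report


def headline_findings(report: dict) -> list[str]:
    """Cohort-level Bonferroni-corrected findings in a report."""
    return list(report.get("headline", {}).get("group_deficit_tasks", []))


def validate_report(report: dict) -> list[str]:
    """Return a list of missing report sections (empty when valid)."""
    return [s for s in REPORT_SECTIONS if s not in report]


def report_to_json(report: dict) -> dict:
    """JSON-serializable copy of a report."""
    return _jsonable(report)
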