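"""Factor analysis of the neuropsychological battery.

Principal-component extraction on the correlation matrix, eigenvalue > 1
retention, varimax rotation, and regression-method factor scores — the
conventional defaults of commercial statistics packages for this kind of
battery. Variance explained per factor is 100 * eigenvalue / n_variables
(eigenvalues of a correlation matrix sum to the number of variables).

The model is fitted on controls and patients together; per-subject factor
scores are then read off for whichever subjects an analysis needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .groupstats import corr_tests

__all__ = [
    "FactorSolution",
    "PrincipalFactorModel",
    "varimax",
    "fit_factors",
    "variance_explained",
    "factor_psychoacoustic_corr",
]


def variance_explained(eigenvalue: float, n_variables: int) -> float:
    """Per-cent variance a factor explains, 100 * eigenvalue / n_variables."""
    if eigenvalue < 0 or n_variables < 1:
        raise ValueError("eigenvalue must be >= 0 and n_variables >= 1")
    return 100.0 * eigenvalue / n_variables


def varimax(loadings: np.ndarray, max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Varimax rotation of a loading matrix (orthogonal, communality-preserving)."""
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L
    R = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        d_old = d
        B = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (B**3 - (B * np.sum(B**2, axis=0)) / p)
        )
        R = u @ vt
        d = np.sum(s)
        if d_old != 0 and d / d_old < 1 + tol:
            break
    return L @ R


@dataclass
class FactorSolution:
    eigenvalues: np.ndarray  # all n_variables eigenvalues, descending
    variance_explained: np.ndarray  # % per retained factor (unrotated eigenvalues)
    loadings: pd.DataFrame  # variables x retained factors (rotated if requested)
    factor_scores: pd.DataFrame  # subjects x factors (regression method)
    n_variables: int
    rotation: str


class PrincipalFactorModel(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: fit the factor solution, transform to scores.

    Parameters
    ----------
    n_factors : "auto" retains eigenvalues > 1; otherwise an int.
    rotation : "varimax" (default) or "none".

    Attributes (after fit)
    ----------------------
    eigenvalues_, variance_explained_, loadings_, communalities_,
    score_coef_ (standardized-variable -> score weights), columns_.
    """

    def __init__(self, n_factors: int | str = "auto", rotation: str = "varimax"):
        self.n_factors = n_factors
        self.rotation = rotation

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        self.columns_ = list(X.columns)
        data = X.to_numpy(dtype=float)
        complete = np.all(np.isfinite(data), axis=1)
        if complete.sum() < data.shape[1] / 2:
            raise ValueError("too few complete-case subjects to fit factors")
        Z = data[complete]
        self.mean_ = Z.mean(axis=0)
        self.std_ = Z.std(axis=0, ddof=1)
        if np.any(self.std_ == 0):
            bad = [c for c, s in zip(self.columns_, self.std_) if s == 0]
            raise ValueError(f"constant variables: {bad}")
        Zs = (Z - self.mean_) / self.std_
        R = np.corrcoef(Zs, rowvar=False)
        cond = np.linalg.cond(R)
        if cond > 1e10:
            raise ValueError(f"singular correlation matrix (condition number {cond:.3g})")
        eigval, eigvec = np.linalg.eigh(R)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        self.eigenvalues_ = eigval
        if self.n_factors == "auto":
            k = int(np.sum(eigval > 1.0))
            k = max(k, 1)
        else:
            k = int(self.n_factors)
        self.n_factors_ = k
        self.variance_explained_ = np.array(
            [variance_explained(e, len(self.columns_)) for e in eigval[:k]]
        )
        L = eigvec[:, :k] * np.sqrt(eigval[:k])
        if self.rotation == "varimax":
            L = varimax(L)
            # order rotated factors by explained sum of squares, largest first
            ss = np.sum(L**2, axis=0)
            L = L[:, np.argsort(ss)[::-1]]
        elif self.rotation != "none":
            raise ValueError("rotation must be 'varimax' or 'none'")
        # sign convention: dominant loading of each factor positive
        for j in range(L.shape[1]):
            if L[np.argmax(np.abs(L[:, j])), j] < 0:
                L[:, j] = -L[:, j]
        self.loadings_ = pd.DataFrame(
            L, index=self.columns_,
            columns=[f"factor{j + 1}" for j in range(k)])
        self.communalities_ = pd.Series(np.sum(L**2, axis=1), index=self.columns_)
        # regression (Thurstone) factor scores: F = Z R^-1 L
        self.score_coef_ = np.linalg.solve(R, L)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "loadings_")
        X = pd.DataFrame(X)
        Z = (X[self.columns_].to_numpy(dtype=float) - self.mean_) / self.std_
        scores = Z @ self.score_coef_
        return pd.DataFrame(scores, index=X.index, columns=self.loadings_.columns)


def fit_factors(table: pd.DataFrame, n_factors: int | str = "auto",
                rotation: str = "varimax") -> FactorSolution:
    """Fit the factor model and return the complete solution record."""
    model = PrincipalFactorModel(n_factors=n_factors, rotation=rotation).fit(table)
    scores = model.transform(table)
    return FactorSolution(
        eigenvalues=model.eigenvalues_,
        variance_explained=model.variance_explained_,
        loadings=model.loadings_,
        factor_scores=scores,
        n_variables=len(model.columns_),
        rotation=rotation,
    )


def factor_psychoacoustic_corr(factor_scores: pd.DataFrame, cohort: pd.DataFrame,
                               task_cols: list[str], sided: str = "one",
                               n_tests: int | None = None) -> pd.DataFrame:
    """Pearson correlations of each factor score with each task outcome,
    Bonferroni-corrected by 12 x n_factors (one-tailed by default)."""
    if factor_scores.isna().all(axis=None):
        raise ValueError("missing factor scores")
    k = factor_scores.shape[1]
    m = n_tests if n_tests is not None else len(task_cols) * k
    joined = cohort.join(factor_scores, how="inner")
    frames = []
    for f in factor_scores.columns:
        t = corr_tests(joined, f, task_cols, method="pearson", sided=sided, n_tests=m)
        t.insert(0, "factor", f)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
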