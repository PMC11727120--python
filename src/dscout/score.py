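"""Six-marker digital scoring: log2(x+1), Z-scores, AHP weights, composite
score, logistic combination and ROC diagnostics.

The composite diagnostic score for a sample is the weighted sum of its
per-marker Z-scores,

    score_i = sum_j w_j * z_ij,   z_ij = (log2(x_ij + 1) - mu_j) / sigma_j,

where the weights w come from the Analytic Hierarchy Process: the
principal right eigenvector of a reciprocal pairwise-comparison matrix,
normalized to sum 1, with Saaty's consistency ratio guarding against
incoherent judgments. The reference population for (mu_j, sigma_j)
defaults to the whole analyzed batch and can be restricted (e.g. to the
healthy cohort) for diagnostic scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import MARKERS

__all__ = [
    "ScoreResult",
    "RocResult",
    "LogisticResult",
    "transform_counts",
    "zscore_matrix",
    "ahp_weights",
    "consistent_comparison_matrix",
    "composite_score",
    "score_cohort",
    "logistic_combine",
    "roc_analysis",
]

# Saaty random consistency indices, indexed by matrix order n
_SAATY_RI = {1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49}


@dataclass
class ScoreResult:
    z: pd.DataFrame  # samples x markers z-scores
    weights: pd.Series  # marker -> weight, sums to 1
    composite: pd.Series  # sample -> weighted Z-score
    ref_mean: pd.Series
    ref_sd: pd.Series
    reference: str  # which population defined (mu, sigma)
    warnings: tuple[str, ...] = ()


@dataclass
class RocResult:
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    curve: pd.DataFrame  # columns: threshold, sensitivity, specificity


@dataclass
class LogisticResult:
    coef: np.ndarray
    intercept: float
    probabilities: np.ndarray
    separation: bool


def transform_counts(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2(x + 1) of the marker columns."""
    out = matrix.copy()
    cols = [c for c in matrix.columns if c in MARKERS] or list(
        matrix.select_dtypes("number").columns
    )
    vals = out[cols].to_numpy(float)
    if (vals < 0).any():
        raise ValueError("copy numbers must be nonnegative")
    out[cols] = np.log2(vals + 1.0)
    return out


def zscore_matrix(
    matrix: pd.DataFrame, reference: str = "all", cohort_col: str = "cohort"
) -> tuple[pd.DataFrame, pd.Series, pd.Series, tuple[str, ...]]:
    """Per-marker standardization against a reference population.

    ``reference`` is "all" or a cohort label; the reference's per-marker
    mean and sd (n-1) define z = (x - mu)/sigma for every sample. Markers
    constant in the reference get all-zero z-scores plus a recorded
    warning. Returns (z, mu, sigma, warnings).
    """
    cols = [c for c in matrix.columns if c in MARKERS] or list(
        matrix.select_dtypes("number").columns
    )
    if reference == "all":
        ref = matrix
    else:
        if cohort_col not in matrix.columns:
            raise ValueError(f"no {cohort_col!r} column to select reference from")
        ref = matrix[matrix[cohort_col] == reference]
    if ref.shape[0] < 2:
        raise ValueError("reference population needs >= 2 samples")
    mu = ref[cols].mean()
    sd = ref[cols].std(ddof=1)
    warnings = tuple(f"constant marker {c!r}: z set to 0" for c in cols if sd[c] == 0)
    safe_sd = sd.replace(0.0, np.nan)
    z = matrix.copy()
    z[cols] = ((matrix[cols] - mu) / safe_sd).fillna(0.0)
    return z, mu, sd, warnings


def consistent_comparison_matrix(weights: Sequence[float]) -> np.ndarray:
    """Build the perfectly consistent pairwise matrix a_ij = w_i / w_j."""
    w = np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    return w[:, None] / w[None, :]


def ahp_weights(
    matrix: np.ndarray, *, allow_inconsistent: bool = False, tol: float = 1e-10
) -> tuple[np.ndarray, float]:
    """AHP criterion weights and consistency ratio from a pairwise matrix.

    The weight vector is the principal right eigenvector (power iteration
    to ``tol``), normalized to sum 1. Consistency index
    CI = (lambda_max - n)/(n - 1); CR = CI / RI with Saaty's random
    indices. CR > 0.1 raises unless ``allow_inconsistent`` is set.
    """
    A = np.asarray(matrix, dtype=float)
    n = A.shape[0]
    if A.ndim != 2 or A.shape[1] != n:
        raise ValueError("comparison matrix must be square")
    if (A <= 0).any():
        raise ValueError("comparison matrix entries must be positive")
    if not np.allclose(A * A.T, 1.0, atol=1e-9):
        raise ValueError("comparison matrix must be reciprocal (a_ji = 1/a_ij)")
    if A.max() > 9.0 + 1e-9 or A.min() < 1.0 / 9.0 - 1e-12:
        raise ValueError("comparison entries must lie in [1/9, 9]")
    w = np.full(n, 1.0 / n)
    for _ in range(10_000):
        w_new = A @ w
        w_new /= w_new.sum()
        if np.abs(w_new - w).max() < tol:
            w = w_new
            break
        w = w_new
    lam_max = float(np.mean((A @ w) / w))
    ci = (lam_max - n) / (n - 1) if n > 1 else 0.0
    ri = _SAATY_RI.get(n)
    if ri is None:
        raise ValueError(f"no Saaty random index for n={n}")
    cr = 0.0 if ri == 0.0 else ci / ri
    if cr > 0.1 and not allow_inconsistent:
        raise ValueError(f"inconsistent comparisons: CR = {cr:.3f} > 0.1")
    return w, float(cr)


def composite_score(z: pd.DataFrame, weights: pd.Series | dict) -> pd.Series:
    """Per-sample weighted sum of marker z-scores."""
    weights = pd.Series(weights, dtype=float)
    missing = [m for m in weights.index if m not in z.columns]
    if missing:
        raise ValueError(f"z matrix missing markers: {missing}")
    return z[list(weights.index)].to_numpy(float) @ weights.to_numpy(float) + pd.Series(
        0.0, index=z.index
    )


def score_cohort(
    matrix: pd.DataFrame,
    weights: pd.Series | dict | None = None,
    reference: str = "all",
) -> ScoreResult:
    """End-to-end scoring: log2(x+1) -> z-scores -> weighted composite.

    With no weights given, markers are weighted equally (a neutral AHP
    matrix of ones). The z and composite columns keep the input's index.
    """
    cols = [c for c in matrix.columns if c in MARKERS]
    if not cols:
        raise ValueError("matrix has no recognized marker columns")
    logm = transform_counts(matrix)
    z, mu, sd, warns = zscore_matrix(logm, reference=reference)
    if weights is None:
        w_vec, _ = ahp_weights(np.ones((len(cols), len(cols))))
        weights = pd.Series(w_vec, index=cols)
    else:
        weights = pd.Series(weights, dtype=float)
    comp = composite_score(z, weights)
    return ScoreResult(
        z=z[cols],
        weights=weights,
        composite=comp,
        ref_mean=mu,
        ref_sd=sd,
        reference=reference,
        warnings=warns,
    )


def logistic_combine(
    features: np.ndarray, labels: Sequence[int], ridge: float = 1e-6
) -> LogisticResult:
    """Ridge-stabilized binary logistic regression.

    A small L2 penalty keeps the maximum-likelihood fit finite under
    perfect separation (flagged when the training data are classified
    without error at large margin).
    """
    from sklearn.linear_model import LogisticRegression

    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    if counts.min() < 2:
        raise ValueError("need >= 2 samples per class")
    clf = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=10_000, tol=1e-10)
    clf.fit(X, y)
    proba = clf.predict_proba(X)[:, 1]
    margin = clf.decision_function(X)
    separation = bool(np.all((margin > 0) == (y == classes.max())) and np.abs(margin).min() > 2.0)
    return LogisticResult(
        coef=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        probabilities=proba,
        separation=separation,
    )


def roc_analysis(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """Rank-statistic AUC and the Youden-optimal operating point.

    AUC is the Mann-Whitney U statistic over positive-negative pairs with
    half-credit for ties. The cutoff maximizes Youden's
    J = sensitivity + specificity - 1 over rules "score >= t -> positive";
    ties in J break toward higher specificity.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.size != y.size or s.size == 0:
        raise ValueError("scores and labels must be equal-length and nonempty")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    from scipy.stats import rankdata

    ranks = rankdata(s)  # midranks: ties get half credit in U
    u = float(ranks[y == 1].sum()) - n1 * (n1 + 1) / 2.0
    auc = u / (n1 * n0)

    thresholds = np.unique(s)
    rows = []
    best = None
    for t in thresholds:
        pred = s >= t
        sens = float((pred & (y == 1)).sum()) / n1
        spec = float((~pred & (y == 0)).sum()) / n0
        rows.append((float(t), sens, spec))
        j = sens + spec - 1.0
        key = (j, spec)
        if best is None or key > best[0]:
            best = (key, float(t), sens, spec)
    _, cutoff, sens, spec = best
    curve = pd.DataFrame(rows, columns=["threshold", "sensitivity", "specificity"])
    return RocResult(auc=float(auc), cutoff=cutoff, sensitivity=sens, specificity=spec, curve=curve)
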