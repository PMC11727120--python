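"""2D protein-mRNA molecular profiling of CTC samples.

Because the number of CTCs captured varies between samples, raw copy
numbers of a marker are not comparable across patients. Dividing each
marker's copies by the sample's ASGPR-protein copies (a liver-lineage
surface marker present on the captured cells, plus a pseudocount) rescales
every sample to an approximately per-cell level, giving each sample a 2D
coordinate (calibrated mRNA, calibrated protein) per marker (EpCAM and
GPC-3).

On this plane a two-class classifier (SVC with linear/poly/rbf kernels, or
a Gaussian naive Bayes baseline) trained on healthy-vs-disease samples
splits the plane into region P1 — the side holding the healthy-cohort
centroid (no CTCs, or CTCs silent for the marker) — and region P2
(marker-expressing CTC profiles). Treatment response is summarized by the
*efficacy vector*: the displacement of a patient's calibrated coordinates
from pre- to post-treatment, with magnitude and direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RegionModel",
    "EfficacyVector",
    "asgpr_calibrate",
    "fit_region_classifier",
    "assign_regions",
    "region_proportions",
    "efficacy_vector",
    "combine_vectors",
    "spearman_corr",
]

_KERNELS = ("linear", "poly", "rbf", "gsnb")


@dataclass
class RegionModel:
    """Trained 2-class region classifier over calibrated 2D coordinates."""

    pipeline: object  # fitted sklearn estimator (scaler + SVC, or GaussianNB)
    kernel: str
    p1_class: object  # predicted class label mapped to region P1
    train_accuracy: float
    cv_metrics: dict[str, float]  # accuracy / precision / recall / f1 (stratified k-fold)
    seed: int
    symlog: bool = True  # whether coordinates are symlog-compressed before the pipeline


def _symlog(x: np.ndarray) -> np.ndarray:
    """sign(v) * log1p(|v|): monotone per axis, identity-like near zero,
    compresses the heavy upper tail of copy-ratio coordinates."""
    return np.sign(x) * np.log1p(np.abs(x))


@dataclass(frozen=True)
class EfficacyVector:
    marker: str
    dx: float
    dy: float

    @property
    def magnitude(self) -> float:
        return math.hypot(self.dx, self.dy)

    @property
    def angle_deg(self) -> float:
        """Degrees counterclockwise from +x, in [0, 360); NaN for the zero
        vector (direction undefined)."""
        if self.dx == 0.0 and self.dy == 0.0:
            return float("nan")
        return math.degrees(math.atan2(self.dy, self.dx)) % 360.0


def asgpr_calibrate(
    profile: pd.DataFrame | pd.Series | dict, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-cell-level 2D coordinates from a six-marker copy profile.

    Each marker's copies are divided by (ASGPR protein copies +
    pseudocount). Returns one row per marker in {EpCAM, GPC3} with columns
    ``sample_id, marker, x, y`` where x is the calibrated mRNA level and y
    the calibrated protein level. Accepts a single profile (Series/dict)
    or a cohort matrix (DataFrame with one row per sample).
    """
    if isinstance(profile, pd.DataFrame):
        parts = [asgpr_calibrate(row, pseudocount) for _, row in profile.iterrows()]
        return pd.concat(parts, ignore_index=True)
    row = pd.Series(profile)
    if "ASGPR_protein" not in row or pd.isna(row["ASGPR_protein"]):
        raise ValueError("ASGPR protein copies required for calibration")
    denom = float(row["ASGPR_protein"]) + pseudocount
    recs = []
    for marker in ("EpCAM", "GPC3"):
        recs.append(
            {
                "sample_id": row.get("sample_id", ""),
                "cohort": row.get("cohort", ""),
                "marker": marker,
                "x": float(row[f"{marker}_mRNA"]) / denom,
                "y": float(row[f"{marker}_protein"]) / denom,
            }
        )
    return pd.DataFrame(recs)


def fit_region_classifier(
    points: np.ndarray,
    labels: Sequence[str],
    kernel: str = "poly",
    seed: int = 0,
    healthy_label: str = "HD",
    symlog: bool = True,
) -> RegionModel:
    """Train the P1/P2 boundary on calibrated 2D points.

    Coordinates are symlog-compressed (sign(v) log1p(|v|); monotone per
    axis, so regions in the original plane stay contiguous) unless
    ``symlog=False`` — calibrated copy ratios are heavy-tailed, and on the
    raw linear scale the tail sets the standardization scale and collapses
    the healthy cluster. Features are then standardized on the training
    set; the classifier is an SVC (poly kernel degree 3, C = 1, coef0 = 1
    by default) or Gaussian naive Bayes for ``kernel="gsnb"``. P1 is the
    side of the boundary containing the healthy-cohort centroid.
    Accuracy/precision/recall/F1 are reported via stratified k-fold
    cross-validation (k = 5, reduced with a warning if a class is
    smaller).
    """
    import warnings as _warnings

    from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score
    from sklearn.model_selection import StratifiedKFold, cross_val_predict
    from sklearn.naive_bayes import GaussianNB
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    X = np.asarray(points, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("points must be (n, 2) with one label per point")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    if counts.min() < 3:
        raise ValueError("need >= 3 points per class")
    if healthy_label not in classes:
        raise ValueError(f"healthy label {healthy_label!r} absent from labels")
    if kernel not in _KERNELS:
        raise ValueError(f"kernel must be one of {_KERNELS}")

    Xt = _symlog(X) if symlog else X
    if kernel == "gsnb":
        pipe = make_pipeline(StandardScaler(), GaussianNB())
    else:
        # coef0=1 gives the poly kernel its lower-order terms; without them
        # the homogeneous (x.y)^3 kernel degenerates on offset clusters
        pipe = make_pipeline(
            StandardScaler(),
            SVC(kernel=kernel, degree=3, C=1.0, coef0=1.0, random_state=seed),
        )
    pipe.fit(Xt, y)
    train_acc = float(accuracy_score(y, pipe.predict(Xt)))

    k = min(5, int(counts.min()))
    if k < 5:
        _warnings.warn(f"smallest class has {counts.min()} points; k-fold reduced to k={k}")
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pred = cross_val_predict(pipe, Xt, y, cv=cv)
    pos = classes[classes != healthy_label][0]
    cv_metrics = {
        "accuracy": float(accuracy_score(y, pred)),
        "precision": float(precision_score(y, pred, pos_label=pos, zero_division=0)),
        "recall": float(recall_score(y, pred, pos_label=pos, zero_division=0)),
        "f1": float(f1_score(y, pred, pos_label=pos, zero_division=0)),
    }

    centroid = Xt[y == healthy_label].mean(axis=0, keepdims=True)
    p1_class = pipe.predict(centroid)[0]
    return RegionModel(
        pipeline=pipe,
        kernel=kernel,
        p1_class=p1_class,
        train_accuracy=train_acc,
        cv_metrics=cv_metrics,
        seed=seed,
        symlog=symlog,
    )


def assign_regions(points: np.ndarray, model: RegionModel) -> np.ndarray:
    """Deterministic P1/P2 label per point (P1 = healthy-centroid side)."""
    X = np.asarray(points, dtype=float)
    if model.symlog:
        X = _symlog(X)
    pred = model.pipeline.predict(X)
    return np.where(pred == model.p1_class, "P1", "P2")


def region_proportions(assignments: Sequence[str], cohorts: Sequence[str]) -> pd.DataFrame:
    """Per-cohort P1/P2 fractions (each row sums to 1)."""
    df = pd.DataFrame({"region": list(assignments), "cohort": list(cohorts)})
    if df.empty:
        raise ValueError("no assignments")
    rows = []
    for cohort, g in df.groupby("cohort", sort=True):
        n = len(g)
        p2 = float((g["region"] == "P2").sum()) / n
        rows.append({"cohort": cohort, "P1": 1.0 - p2, "P2": p2, "n": n})
    return pd.DataFrame(rows)


def efficacy_vector(
    pre: tuple[float, float], post: tuple[float, float], marker: str = ""
) -> EfficacyVector:
    """Displacement of calibrated coordinates from pre- to post-treatment."""
    return EfficacyVector(marker=marker, dx=float(post[0] - pre[0]), dy=float(post[1] - pre[1]))


def combine_vectors(*vectors: EfficacyVector, marker: str = "combined") -> EfficacyVector:
    """Componentwise sum, e.g. integrating EpCAM and GPC-3 responses."""
    if not vectors:
        raise ValueError("need at least one vector")
    return EfficacyVector(
        marker=marker, dx=sum(v.dx for v in vectors), dy=sum(v.dy for v in vectors)
    )


def spearman_corr(
    x: Sequence[float], y: Sequence[float], n_perm: int = 9999, seed: int = 0
) -> tuple[float, float]:
    """Spearman rank correlation with a permutation p-value.

    r is the Pearson correlation of midranks (average ranks on ties); the
    two-sided p-value counts permutations of y whose |r| reaches the
    observed |r|, over ``n_perm`` seeded shuffles (+1 smoothing).
    Constant input has no defined rank correlation and raises.
    """
    from scipy.stats import rankdata

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("rank correlation undefined for a constant vector")
    rx = rankdata(x)
    ry = rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    n = x.size
    r_obs = float(rx @ ry) / n
    rng = np.random.default_rng([seed, 17])
    count = 0
    for _ in range(n_perm):
        r = float(rx @ rng.permutation(ry)) / n
        if abs(r) >= abs(r_obs) - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return r_obs, float(p)
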