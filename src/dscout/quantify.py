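"""Absolute quantification from partition counts, and assay analytics.

Digital PCR distributes template molecules over N partitions; with M of
them positive, the Poisson occupancy model inverts the fraction of empty
partitions to an absolute copy number per reaction::

    X = -N * ln(1 - M / N)

A 95% interval on X is obtained from the Wilson score interval on the
positive fraction p = M/N pushed through the same transform (the transform
is monotone, so interval endpoints map directly).

Also here: the assay-validation statistics — nonparametric limit of blank
(LOB), probit-regression limit of detection (LOD at 95% detection),
percentage coefficient of variation, standard curves with r^2, qPCR
amplification efficiency from dilution-series Ct slopes, and the
2^-ddCt relative-quantification comparison utility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .simulate import HitTable

__all__ = [
    "ChannelQuant",
    "LoBLoDResult",
    "StandardCurve",
    "poisson_quantify",
    "lob",
    "lod_probit",
    "percent_cv",
    "standard_curve",
    "qpcr_efficiency",
    "ddct_fold_change",
]


@dataclass(frozen=True)
class ChannelQuant:
    """Copies per reaction from an (M positive / N total) partition count."""

    M: int
    N: int
    X: float
    ci_low: float
    ci_high: float
    saturated: bool = False


@dataclass(frozen=True)
class LoBLoDResult:
    lob: float
    lod: float
    intercept: float  # probit intercept a (on log10 concentration)
    slope: float  # probit slope b
    converged: bool


@dataclass(frozen=True)
class StandardCurve:
    slope: float
    intercept: float
    r2: float
    x_range: tuple[float, float]


def _wilson(M: float, N: int, z: float = 1.959963984540054) -> tuple[float, float]:
    p = M / N
    denom = 1.0 + z**2 / N
    center = (p + z**2 / (2 * N)) / denom
    half = (z / denom) * math.sqrt(p * (1 - p) / N + z**2 / (4 * N**2))
    return max(center - half, 0.0), min(center + half, 1.0)


def poisson_quantify(M: int, N: int) -> ChannelQuant:
    """Poisson copies per reaction with a Wilson-propagated 95% interval.

    Saturated plates (M = N, where the transform diverges) are reported at
    M - 0.5 with ``saturated=True``.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if not (0 <= M <= N):
        raise ValueError("M must lie in [0, N]")
    saturated = M == N
    M_eff = M - 0.5 if saturated else float(M)
    X = -N * math.log(1.0 - M_eff / N)
    p_lo, p_hi = _wilson(M_eff, N)
    ci_low = -N * math.log(1.0 - p_lo)
    ci_high = -N * math.log(1.0 - p_hi) if p_hi < 1.0 else -N * math.log(0.5 / N)
    return ChannelQuant(
        M=int(M), N=int(N), X=X, ci_low=ci_low, ci_high=ci_high, saturated=saturated
    )


def lob(blank_values: Sequence[float], percentile: float = 0.95) -> float:
    """Nonparametric limit of blank: the interpolated percentile of blanks.

    Rank r = 0.5 + percentile * n; the LOB interpolates linearly between
    the adjacent order statistics and is clipped to the observed range
    (CLSI-style convention).
    """
    x = np.sort(np.asarray(blank_values, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("need >= 2 blank measurements")
    if not (0.0 < percentile < 1.0):
        raise ValueError("percentile must be in (0, 1)")
    r = 0.5 + percentile * n
    if r <= 1.0:
        return float(x[0])
    if r >= n:
        return float(x[-1])
    lo = int(math.floor(r))
    frac = r - lo
    return float(x[lo - 1] + frac * (x[lo] - x[lo - 1]))


def lod_probit(hits: HitTable, target_p: float = 0.95) -> LoBLoDResult:
    """Probit-regression LOD: the concentration detected with ``target_p``
    probability.

    Fits detection ~ probit(a + b * log10(conc)) by binomial maximum
    likelihood; LOD = 10**((Phi^-1(target_p) - a) / b). If every row is
    fully detected there is nothing to regress on: the lowest tested
    concentration is returned with ``converged=False``. A non-positive
    slope (detection not improving with concentration) is likewise flagged.
    """
    import statsmodels.api as sm
    from scipy.stats import norm

    df = hits.to_frame()
    if df["concentration"].nunique() < 3:
        raise ValueError("need >= 3 distinct concentrations")
    if not (0.0 < target_p < 1.0):
        raise ValueError("target_p must be in (0, 1)")
    lowest = float(df["concentration"].min())
    if (df["n_detected"] == df["n_replicates"]).all():
        return LoBLoDResult(
            lob=float("nan"), lod=lowest, intercept=float("nan"), slope=float("nan"),
            converged=False,
        )
    X = sm.add_constant(np.log10(df["concentration"].to_numpy(float)))
    y = np.column_stack(
        [df["n_detected"].to_numpy(float), (df["n_replicates"] - df["n_detected"]).to_numpy(float)]
    )
    model = sm.GLM(y, X, family=sm.families.Binomial(link=sm.families.links.Probit()))
    try:
        res = model.fit()
        a, b = float(res.params[0]), float(res.params[1])
        fit_ok = bool(res.converged)
    except Exception:
        a, b, fit_ok = float("nan"), float("nan"), False
    if not fit_ok or not (b > 0):
        return LoBLoDResult(lob=float("nan"), lod=lowest, intercept=a, slope=b, converged=False)
    lod = 10.0 ** ((norm.ppf(target_p) - a) / b)
    return LoBLoDResult(lob=float("nan"), lod=float(lod), intercept=a, slope=b, converged=True)


def percent_cv(values: Sequence[float]) -> float:
    """100 * sample sd (n-1 denominator) / mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("%CV undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / mean)


def standard_curve(x: Sequence[float], y: Sequence[float]) -> StandardCurve:
    """Ordinary least squares of copies on cell count, with r^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 paired points")
    if np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct x values")
    slope, intercept = np.polyfit(x, y, 1)
    yhat = intercept + slope * x
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return StandardCurve(
        slope=float(slope), intercept=float(intercept), r2=r2,
        x_range=(float(x.min()), float(x.max())),
    )


def qpcr_efficiency(cts: Sequence[float], concentrations: Sequence[float]) -> float:
    """Amplification efficiency (%) from a dilution series.

    Fits Ct against log10(concentration); efficiency is
    ``(10**(-1/slope) - 1) * 100`` (100% = perfect doubling per cycle,
    slope -1/log10(2) = -3.32).
    """
    cts = np.asarray(cts, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    if cts.size < 3 or cts.size != conc.size:
        raise ValueError("need >= 3 dilution points")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    logc = np.log10(conc)
    if logc.max() - logc.min() < 2.0 - 1e-9:
        raise ValueError("dilution series must span >= 2 logs")
    slope = np.polyfit(logc, cts, 1)[0]
    if slope >= 0:
        raise ValueError("non-negative Ct-vs-log10(conc) slope: no amplification trend")
    return float((10.0 ** (-1.0 / slope) - 1.0) * 100.0)


def ddct_fold_change(
    ct_target_case: float, ct_ref_case: float, ct_target_ctrl: float, ct_ref_ctrl: float
) -> float:
    """Relative quantification 2**-ddCt (classic qPCR comparison)."""
    for v in (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl):
        if not math.isfinite(v):
            raise ValueError("all Ct values must be finite")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0**-ddct)
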