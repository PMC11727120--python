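"""Per-microwell amplification-curve analysis and positive/negative calling.

Each microwell of the digital PCR chip is monitored in every cycle, giving
one fluorescence trace per well x dye channel. A well is called positive
only if its whole curve looks like real amplification: the trace is fitted
with a four-parameter logistic on a drifting baseline,

    F(c) = F0 + drift * c + A / (1 + exp(-k * (c - c50))),

and the call combines curve shape (fit r^2), signal size (amplitude vs the
well's baseline noise), the threshold-crossing cycle Ct, and the normalized
fluorescence growth rate (max slope of the amplitude-1 logistic, k/4).
This guards against the failure modes of endpoint-only thresholding:
drifting baselines, late nonspecific creep-up, and bright outlier noise.

The closed forms used throughout:

* Ct at threshold fraction f of the amplitude: ``Ct = c50 - ln(1/f - 1)/k``
* normalized growth rate: ``k / 4``;  un-normalized: ``A * k / 4``

Least-squares fitting operates on the raw trace; the moving-average
smoother is used for noise-robust candidate screening, initialization and
display. (Fitting the smoothed trace would bias the logistic rate low —
a boxcar flattens the sigmoid — and with it every derived Ct.)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

from .simulate import CT_THRESHOLD_FRAC, PlateRun, TraceBlock

__all__ = [
    "FluorescenceTrace",
    "CurveFit",
    "WellCall",
    "CallCriteria",
    "PlateCalls",
    "smooth_trace",
    "fit_amplification_curve",
    "compute_ct",
    "compute_growth_rate",
    "classify_well",
    "call_plate",
]

# Default per-channel floor on the normalized growth rate: a quarter of the
# channel's nominal mean rate. Low enough that the natural spread of real
# positives (sd 0.07-0.15) essentially never falls below it, high enough to
# reject slow nonspecific drift-ups.
DEFAULT_MIN_GROWTH_RATE = {"FAM": 0.0975, "VIC": 0.165, "CY5": 0.0625}


@dataclass
class FluorescenceTrace:
    """One well x channel intensity series over cycles."""

    region: str
    well_id: int | str
    channel: str
    intensities: np.ndarray
    cycles: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1 or self.intensities.size < 2:
            raise ValueError("trace needs >= 2 cycles")
        if not np.isfinite(self.intensities).all():
            raise ValueError("trace intensities must be finite")
        if self.cycles is None:
            self.cycles = np.arange(1, self.intensities.size + 1)
        else:
            self.cycles = np.asarray(self.cycles)
            if self.cycles.size != self.intensities.size:
                raise ValueError("cycles/intensities length mismatch")


@dataclass
class CurveFit:
    """Fitted 4PL-plus-drift parameters for one trace."""

    F0: float
    drift: float
    A: float
    k: float
    c50: float
    r2: float
    converged: bool
    noise_sd: float = float("nan")  # baseline noise estimate for the amplitude test


@dataclass
class WellCall:
    region: str
    well_id: int | str
    channel: str
    ct: float  # NaN when absent
    growth_rate: float
    positive: bool
    reasons: tuple[str, ...]  # criteria failed (empty for positives)
    r2: float


@dataclass(frozen=True)
class CallCriteria:
    """Conjunctive positivity rule: every criterion must pass.

    ``min_amplitude_snr`` is the amplitude floor as a multiple of the
    well's baseline noise sd (estimated from residuals of a linear fit to
    the first ``baseline_cycles`` cycles).
    """

    min_r2: float = 0.98
    min_amplitude_snr: float = 5.0
    ct_window: tuple[float, float] = (10.0, 38.0)
    min_growth_rate: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIN_GROWTH_RATE)
    )
    smoothing_window: int = 5
    baseline_cycles: int = 8
    ct_threshold_frac: float = CT_THRESHOLD_FRAC

    def __post_init__(self) -> None:
        if self.smoothing_window < 3 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing window must be odd and >= 3")
        lo, hi = self.ct_window
        if not (0 < lo < hi):
            raise ValueError("invalid ct_window")
        if not (0.0 < self.ct_threshold_frac < 1.0):
            raise ValueError("ct_threshold_frac must be in (0, 1)")


@dataclass
class PlateCalls:
    """Per-well calls plus per-(region, channel) summaries.

    ``summary`` columns: region, channel, M, N, ct_mean, ct_sd, rate_mean,
    rate_sd (Ct/rate statistics over positive wells only).
    """

    calls: pd.DataFrame
    summary: pd.DataFrame

    def counts(self, region: str, channel: str) -> tuple[int, int]:
        row = self.summary[
            (self.summary["region"] == region) & (self.summary["channel"] == channel)
        ]
        if row.empty:
            raise KeyError(f"no calls for region={region!r} channel={channel!r}")
        return int(row["M"].iloc[0]), int(row["N"].iloc[0])


# ---------------------------------------------------------------------------
# smoothing


def _smooth_matrix(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along the last axis; symmetric shrinking
    windows at the edges (so linear signals are exact fixed points)."""
    n = x.shape[-1]
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if window > n:
        raise ValueError("window longer than trace")
    half = window // 2
    out = np.empty_like(x, dtype=float)
    csum = np.cumsum(np.concatenate([np.zeros(x.shape[:-1] + (1,)), x], axis=-1), axis=-1)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[..., i] = (csum[..., i + h + 1] - csum[..., i - h]) / (2 * h + 1)
    return out


def smooth_trace(trace: FluorescenceTrace, window: int = 5) -> FluorescenceTrace:
    """Moving-average smoothing; same length, edges use shrinking windows."""
    y = _smooth_matrix(trace.intensities[None, :], window)[0]
    return FluorescenceTrace(
        region=trace.region,
        well_id=trace.well_id,
        channel=trace.channel,
        intensities=y,
        cycles=trace.cycles.copy(),
    )


# ---------------------------------------------------------------------------
# fitting


def _model(c, F0, drift, A, k, c50):
    return F0 + drift * c + A / (1.0 + np.exp(-np.clip(k * (c - c50), -500, 500)))


def _model_jac(c, F0, drift, A, k, c50):
    s = 1.0 / (1.0 + np.exp(-np.clip(k * (c - c50), -500, 500)))
    ds = s * (1.0 - s)
    J = np.empty((c.size, 5))
    J[:, 0] = 1.0
    J[:, 1] = c
    J[:, 2] = s
    J[:, 3] = A * (c - c50) * ds
    J[:, 4] = -A * k * ds
    return J


def _baseline_fit(c: np.ndarray, y: np.ndarray, n_base: int) -> tuple[float, float, float]:
    """Linear fit to the first n_base cycles; returns (b0, b1, noise_sd)."""
    nb = min(max(n_base, 3), y.size)
    cb, yb = c[:nb], y[:nb]
    b1, b0 = np.polyfit(cb, yb, 1)
    resid = yb - (b0 + b1 * cb)
    dof = max(nb - 2, 1)
    return float(b0), float(b1), float(np.sqrt(np.sum(resid**2) / dof))


def _fit_array(c: np.ndarray, y: np.ndarray, baseline_cycles: int = 8) -> CurveFit:
    if y.size < 6:
        raise ValueError("cannot fit amplification curve with fewer than 6 cycles")
    b0, b1, noise_sd = _baseline_fit(c, y, baseline_cycles)
    y_s = _smooth_matrix(y[None, :], min(5, y.size - (1 - y.size % 2)))[0]
    rng_y = float(y.max() - y.min())
    d1 = np.diff(y_s)
    c50_0 = float(c[int(np.argmax(d1))]) if d1.size else float(c[y.size // 2])
    # rate init from the steepest smoothed rise: max slope of a logistic is
    # A*k/4 (the smoothed slope underestimates it, so this is a floor)
    k0 = 0.5
    if d1.size and rng_y > 0:
        k0 = min(max(4.0 * float(d1.max()) / rng_y, 0.2), 8.0)
    p0 = [float(y.min()), b1, rng_y, k0, c50_0]
    try:
        with warnings.catch_warnings(), np.errstate(over="ignore", invalid="ignore"):
            warnings.simplefilter("ignore", OptimizeWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            popt, _ = curve_fit(_model, c, y, p0=p0, jac=_model_jac, method="lm", maxfev=400)
        F0, drift, A, k, c50 = (float(v) for v in popt)
        converged = np.isfinite([F0, drift, A, k, c50]).all() and A >= 0 and k > 0
    except (RuntimeError, ValueError):
        converged = False
    if not converged:
        # degenerate fit: report the baseline-only model, A = 0
        F0, drift, A, k, c50 = b0, b1, 0.0, 0.0, float("nan")
    yhat = _model(c, F0, drift, A, k if k else 1.0, c50 if np.isfinite(c50) else 0.0)
    if A == 0.0:
        yhat = F0 + drift * c
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return CurveFit(
        F0=F0, drift=drift, A=A, k=k, c50=c50, r2=r2, converged=bool(converged), noise_sd=noise_sd
    )


def fit_amplification_curve(trace: FluorescenceTrace, baseline_cycles: int = 8) -> CurveFit:
    """Least-squares 4PL-plus-drift fit of one trace.

    Initialization is data-driven (F0 = min, A = range, c50 = cycle of the
    steepest smoothed rise, k = 0.5). Non-convergent fits return
    ``converged=False`` with A = 0; traces shorter than 6 cycles raise.
    """
    return _fit_array(np.asarray(trace.cycles, float), trace.intensities, baseline_cycles)


def compute_ct(fit: CurveFit, threshold_frac: float = CT_THRESHOLD_FRAC) -> float:
    """Threshold-crossing Ct of the drift-corrected fitted curve.

    The logistic component crosses ``threshold_frac * A`` at
    ``c50 - ln(1/threshold_frac - 1) / k`` (may be fractional).
    """
    if not (0.0 < threshold_frac < 1.0):
        raise ValueError("threshold_frac must be in (0, 1)")
    if not fit.converged or fit.A <= 0 or fit.k <= 0:
        raise ValueError("no Ct: fit did not converge or has no amplitude")
    return float(fit.c50 - np.log(1.0 / threshold_frac - 1.0) / fit.k)


def compute_growth_rate(fit: CurveFit, normalized: bool = True) -> float:
    """Maximum slope of the fitted logistic: k/4 normalized, A*k/4 raw."""
    if not fit.converged:
        raise ValueError("no growth rate: fit did not converge")
    rate = fit.k / 4.0
    return float(rate if normalized else fit.A * rate)


def classify_well(
    fit: CurveFit,
    ct: float,
    rate: float,
    criteria: CallCriteria,
    *,
    region: str = "",
    well_id: int | str = -1,
    channel: str = "FAM",
) -> WellCall:
    """Apply the conjunctive positivity rule; failed criteria are named.

    Comparisons are inclusive (a well exactly at a threshold passes).
    Degenerate fits classify as negative, never raise.
    """
    reasons: list[str] = []
    if not fit.converged:
        reasons.append("not_converged")
    if fit.r2 < criteria.min_r2:
        reasons.append("r2")
    noise = fit.noise_sd if np.isfinite(fit.noise_sd) else 0.0
    if fit.A < criteria.min_amplitude_snr * noise or fit.A <= 0:
        reasons.append("amplitude")
    lo, hi = criteria.ct_window
    if not (np.isfinite(ct) and lo <= ct <= hi):
        reasons.append("ct_window")
    min_rate = criteria.min_growth_rate.get(channel, 0.0)
    if not (np.isfinite(rate) and rate >= min_rate):
        reasons.append("growth_rate")
    positive = not reasons
    return WellCall(
        region=region,
        well_id=well_id,
        channel=channel,
        ct=float(ct) if np.isfinite(ct) else float("nan"),
        growth_rate=float(rate) if np.isfinite(rate) else 0.0,
        positive=positive,
        reasons=tuple(reasons),
        r2=fit.r2,
    )


# ---------------------------------------------------------------------------
# whole-plate calling


def _call_block(blk: TraceBlock, criteria: CallCriteria) -> pd.DataFrame:
    c = np.asarray(blk.cycles, float)
    X = blk.intensities
    n_wells, n_cycles = X.shape
    if n_cycles < 6:
        raise ValueError("cannot call a plate with fewer than 6 cycles")

    S = _smooth_matrix(X, min(criteria.smoothing_window, n_cycles - (1 - n_cycles % 2)))

    # vectorized baseline fit on the first baseline_cycles raw cycles
    nb = min(max(criteria.baseline_cycles, 3), n_cycles)
    cb = c[:nb]
    cbar = cb.mean()
    denom = np.sum((cb - cbar) ** 2)
    yb = X[:, :nb]
    b1 = (yb @ (cb - cbar)) / denom
    b0 = yb.mean(axis=1) - b1 * cbar
    resid = yb - (b0[:, None] + b1[:, None] * cb[None, :])
    noise_sd = np.sqrt(np.sum(resid**2, axis=1) / max(nb - 2, 1))

    # Candidate pre-screen (full fits are only spent on wells that could
    # plausibly pass the amplitude criterion):
    #   (a) peak of the smoothed trace above a full-trace linear fit — a
    #       sigmoid leaves a residual peak of ~0.4*A, noise only its own
    #       smoothed maximum, screened at 1/4 of the amplitude floor;
    #   (b) a net rise from the first to the last cycles of at least half
    #       the amplitude floor (or a peak clearing the floor outright,
    #       which admits late risers whose rise is still building).
    # Negatives must fail on chance alone at both (a) and (b); jointly that
    # is < 1e-4 per well at the default criteria.
    # The screen thresholds use a plate-level noise scale (median of the
    # per-well estimates): the per-well estimate has only ~6 degrees of
    # freedom and its low tail would otherwise leak thousands of noise
    # wells into the expensive fit. The amplitude criterion itself keeps
    # the per-well estimate.
    cf = c - c.mean()
    bf1 = (X @ cf) / np.sum(cf**2)
    bf0 = X.mean(axis=1)
    detr = S - (bf0[:, None] + bf1[:, None] * cf[None, :])
    peak = detr.max(axis=1)
    tail = min(5, n_cycles // 2)
    rise = S[:, -tail:].mean(axis=1) - S[:, :tail].mean(axis=1)
    plate_noise = float(np.median(noise_sd))
    floor = criteria.min_amplitude_snr * max(plate_noise, 1e-12)
    candidate = (peak >= 0.25 * floor) & ((rise >= 0.5 * floor) | (peak >= floor))

    ct_arr = np.full(n_wells, np.nan)
    rate_arr = np.zeros(n_wells)
    r2_arr = np.empty(n_wells)
    pos_arr = np.zeros(n_wells, dtype=bool)
    reasons_arr = np.empty(n_wells, dtype=object)

    # non-candidates: baseline-only wells, negative on the amplitude rule
    non_cand = ~candidate
    if non_cand.any():
        yhat = b0[:, None] + b1[:, None] * c[None, :]
        ss_res = np.sum((X - yhat) ** 2, axis=1)
        ss_tot = np.sum((X - X.mean(axis=1, keepdims=True)) ** 2, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2_lin = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
        r2_arr[non_cand] = r2_lin[non_cand]
        reasons_arr[non_cand] = "amplitude"

    for i in np.flatnonzero(candidate):
        fit = _fit_array(c, X[i], criteria.baseline_cycles)
        fit.noise_sd = float(noise_sd[i])  # reuse the vectorized estimate
        try:
            ct = compute_ct(fit, criteria.ct_threshold_frac)
        except ValueError:
            ct = float("nan")
        rate = fit.k / 4.0 if fit.converged else float("nan")
        call = classify_well(
            fit, ct, rate, criteria, region=blk.region, well_id=blk.well_ids[i], channel=blk.channel
        )
        ct_arr[i] = call.ct
        rate_arr[i] = call.growth_rate
        r2_arr[i] = call.r2
        pos_arr[i] = call.positive
        reasons_arr[i] = ";".join(call.reasons)

    return pd.DataFrame(
        {
            "region": blk.region,
            "channel": blk.channel,
            "well_id": blk.well_ids,
            "positive": pos_arr,
            "ct": ct_arr,
            "growth_rate": rate_arr,
            "r2": r2_arr,
            "reasons": reasons_arr,
        }
    )


def call_plate(run: PlateRun, criteria: CallCriteria | None = None) -> PlateCalls:
    """smooth -> fit -> Ct -> rate -> classify for every well x channel x region.

    Deterministic given the input traces and criteria. Returns per-well
    calls and per-(region, channel) summaries: positive count M, analyzed
    wells N, and mean/sd of Ct and growth rate over positives.
    """
    if criteria is None:
        criteria = CallCriteria()
    if not run.blocks:
        raise ValueError("empty plate")
    if len({blk.cycles.size for blk in run.blocks.values()}) > 1:
        raise ValueError("mixed cycle counts across blocks")
    call_parts = [_call_block(blk, criteria) for _, blk in sorted(run.blocks.items())]
    calls = pd.concat(call_parts, ignore_index=True)
    rows = []
    for (region, channel), g in calls.groupby(["region", "channel"], sort=True):
        pos = g[g["positive"]]
        rows.append(
            {
                "region": region,
                "channel": channel,
                "M": int(pos.shape[0]),
                "N": int(g.shape[0]),
                "ct_mean": float(pos["ct"].mean()) if len(pos) else float("nan"),
                "ct_sd": float(pos["ct"].std(ddof=1)) if len(pos) > 1 else float("nan"),
                "rate_mean": float(pos["growth_rate"].mean()) if len(pos) else float("nan"),
                "rate_sd": float(pos["growth_rate"].std(ddof=1)) if len(pos) > 1 else float("nan"),
            }
        )
    return PlateCalls(calls=calls, summary=pd.DataFrame(rows))
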