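"""Synthetic MRT-dPCR plates, dilution series and clinical-style cohorts.

The generators emulate the study conditions of a chip-partitioned,
real-time digital PCR assay: ~20,000 microwells per assay region, each
imaged every cycle in three dye channels, with channel-specific cycle
threshold (Ct) and normalized fluorescence-growth-rate distributions.
Every generator is a pure function of its parameters and an explicit seed,
and each returns its ground truth so downstream calling, quantification and
scoring can be validated against known answers.

Partitioning model
------------------
``round(lam)`` template molecules are placed into ``n_wells`` wells by
independent equal-probability assignment (a multinomial throw), so the
realized total template is conserved exactly and the per-well occupancy is
approximately Poisson(lam / n_wells). The expected number of occupied
(positive) wells is ``N * (1 - exp(-lam/N))``.

Trace model
-----------
A positive well's fluorescence over cycles c = 1..n_cycles is a
four-parameter logistic riding on a drifting baseline::

    F(c) = F0 + drift * c + A / (1 + exp(-k * (c - c50))) + eps,  eps ~ N(0, noise_sd)

The logistic rate ``k`` is back-solved from the drawn normalized growth
rate r (max slope of the amplitude-1 logistic is k/4, so k = 4 r), and the
inflection cycle ``c50`` is placed so that the threshold-crossing Ct at 10%
amplitude equals the drawn channel Ct: c50 = ct + ln(9)/k. Negative wells
carry baseline + drift + noise only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import CHANNELS, MARKERS, REGIONS

__all__ = [
    "PlateSimParams",
    "TraceBlock",
    "PlateRun",
    "CohortDesign",
    "HitTable",
    "simulate_plate",
    "simulate_truth_counts",
    "simulate_cohort",
    "default_cohort_design",
    "simulate_binormal_cohort",
    "simulate_dilution_series",
    "CT_THRESHOLD_FRAC",
]

# Ct is defined as the cycle where the drift-corrected curve crosses this
# fraction of the amplitude; shared with the calling module.
CT_THRESHOLD_FRAC = 0.1

# Channel-level defaults: positive-well Ct and normalized growth-rate
# distributions observed on the instrument (mean, sd per dye).
DEFAULT_CT_MEAN = {"FAM": 26.83, "VIC": 26.46, "CY5": 25.73}
DEFAULT_CT_SD = {"FAM": 0.88, "VIC": 0.86, "CY5": 1.21}
DEFAULT_RATE_MEAN = {"FAM": 0.39, "VIC": 0.66, "CY5": 0.25}
DEFAULT_RATE_SD = {"FAM": 0.07, "VIC": 0.15, "CY5": 0.07}


@dataclass(frozen=True)
class PlateSimParams:
    """Parameters of one simulated multi-region, multi-channel plate.

    ``target_copies`` maps (region, channel) to the template load lambda for
    that assay; omitted pairs default to zero template.
    """

    n_wells: int = 20000
    n_cycles: int = 40
    channels: tuple[str, ...] = CHANNELS
    regions: tuple[str, ...] = REGIONS
    target_copies: Mapping[tuple[str, str], float] = field(default_factory=dict)
    ct_mean: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CT_MEAN))
    ct_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CT_SD))
    growth_rate_mean: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RATE_MEAN))
    growth_rate_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RATE_SD))
    amplitude_mean: float = 1.0
    amplitude_sd: float = 0.05
    baseline_level: float = 0.1
    baseline_drift: float = 0.001
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wells < 1:
            raise ValueError("n_wells must be >= 1")
        if self.n_cycles < 2:
            raise ValueError("n_cycles must be >= 2")
        if int(self.n_wells) * int(self.n_cycles) > 10**9:
            raise ValueError("n_wells * n_cycles too large")
        for (region, channel), lam in self.target_copies.items():
            if lam < 0:
                raise ValueError(f"negative template load for {(region, channel)}")
            if region not in self.regions or channel not in self.channels:
                raise ValueError(f"target_copies key {(region, channel)} not in plate layout")
        for ch in self.channels:
            if not (1.0 < self.ct_mean[ch] < self.n_cycles):
                raise ValueError(f"ct_mean[{ch}] must lie in (1, n_cycles)")
            for m in (self.ct_sd, self.growth_rate_sd):
                if m[ch] < 0:
                    raise ValueError("standard deviations must be >= 0")
        if min(self.amplitude_sd, self.noise_sd) < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass
class TraceBlock:
    """All traces of one (region, channel): an n_wells x n_cycles matrix."""

    region: str
    channel: str
    well_ids: np.ndarray  # (n_wells,) int
    cycles: np.ndarray  # (n_cycles,) int, 1-based
    intensities: np.ndarray  # (n_wells, n_cycles) float


@dataclass
class PlateRun:
    """One plate's fluorescence traces, grouped by (region, channel)."""

    blocks: dict[tuple[str, str], TraceBlock]

    @property
    def n_cycles(self) -> int:
        return next(iter(self.blocks.values())).cycles.size

    def to_frame(self) -> pd.DataFrame:
        """Long-format table ``region,well_id,channel,cycle,intensity``."""
        parts = []
        for (region, channel), blk in sorted(self.blocks.items()):
            n_wells, n_cycles = blk.intensities.shape
            parts.append(
                pd.DataFrame(
                    {
                        "region": region,
                        "well_id": np.repeat(blk.well_ids, n_cycles),
                        "channel": channel,
                        "cycle": np.tile(blk.cycles, n_wells),
                        "intensity": blk.intensities.ravel(),
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PlateRun":
        required = ["region", "well_id", "channel", "cycle", "intensity"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"trace table missing columns: {missing}")
        if df["intensity"].isna().any() or not np.isfinite(df["intensity"].to_numpy(float)).all():
            raise ValueError("non-finite intensity values in trace table")
        dup = df.duplicated(subset=["region", "well_id", "channel", "cycle"])
        if dup.any():
            row = df[dup].iloc[0]
            raise ValueError(
                "duplicate trace row for "
                f"region={row['region']} well={row['well_id']} channel={row['channel']} cycle={row['cycle']}"
            )
        blocks: dict[tuple[str, str], TraceBlock] = {}
        n_cycles_seen: set[int] = set()
        for (region, channel), g in df.groupby(["region", "channel"], sort=True):
            wide = g.pivot(index="well_id", columns="cycle", values="intensity")
            if wide.isna().any().any():
                raise ValueError(f"ragged cycle coverage in region={region} channel={channel}")
            cycles = wide.columns.to_numpy(int)
            if not np.array_equal(cycles, np.arange(cycles[0], cycles[0] + cycles.size)):
                raise ValueError("missing cycles in trace table")
            n_cycles_seen.add(cycles.size)
            blocks[(region, channel)] = TraceBlock(
                region=region,
                channel=channel,
                well_ids=wide.index.to_numpy(),
                cycles=cycles,
                intensities=wide.to_numpy(float),
            )
        if len(n_cycles_seen) > 1:
            raise ValueError("mixed cycle counts across trace blocks")
        if not blocks:
            raise ValueError("empty trace table")
        return cls(blocks=blocks)


def _occupancy_counts(lam: float, n_wells: int, rng: np.random.Generator) -> np.ndarray:
    """Multinomial placement of round(lam) molecules into n_wells wells."""
    n_mol = int(round(lam))
    counts = np.zeros(n_wells, dtype=np.int64)
    if n_mol > 0:
        wells = rng.integers(0, n_wells, size=n_mol)
        np.add.at(counts, wells, 1)
    return counts


def simulate_truth_counts(params: PlateSimParams) -> pd.DataFrame:
    """Ground-truth per-well molecule counts only (no traces).

    Same placement model and seeding scheme as :func:`simulate_plate`, so a
    given (params, seed) yields the identical truth table either way. Useful
    when only occupancy statistics are needed.
    """
    rows = []
    for region in params.regions:
        for channel in params.channels:
            rng = _block_rng(params, region, channel)
            lam = float(params.target_copies.get((region, channel), 0.0))
            counts = _occupancy_counts(lam, params.n_wells, rng)
            rows.append(
                pd.DataFrame(
                    {
                        "region": region,
                        "channel": channel,
                        "well_id": np.arange(params.n_wells),
                        "molecules": counts,
                        "ct_true": np.nan,
                        "lambda_true": lam,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def _block_rng(params: PlateSimParams, region: str, channel: str) -> np.random.Generator:
    # independent, order-insensitive stream per (region, channel)
    return np.random.default_rng(
        [params.seed, params.regions.index(region), params.channels.index(channel)]
    )


def simulate_plate(params: PlateSimParams) -> tuple[PlateRun, pd.DataFrame]:
    """Simulate one plate; return traces and the per-well truth table.

    The truth table has columns ``region, channel, well_id, molecules,
    ct_true, lambda_true``; ``ct_true`` is NaN for empty wells. Identical
    (params, seed) give bit-identical output.
    """
    blocks: dict[tuple[str, str], TraceBlock] = {}
    truth_parts = []
    cycles = np.arange(1, params.n_cycles + 1)
    for region in params.regions:
        for channel in params.channels:
            rng = _block_rng(params, region, channel)
            lam = float(params.target_copies.get((region, channel), 0.0))
            counts = _occupancy_counts(lam, params.n_wells, rng)
            pos = np.flatnonzero(counts > 0)

            intens = np.empty((params.n_wells, params.n_cycles))
            intens[:] = params.baseline_level + params.baseline_drift * cycles

            ct_true = np.full(params.n_wells, np.nan)
            if pos.size:
                ct = rng.normal(params.ct_mean[channel], params.ct_sd[channel], size=pos.size)
                ct = np.clip(ct, 2.0, params.n_cycles - 1.0)
                rate = rng.normal(
                    params.growth_rate_mean[channel], params.growth_rate_sd[channel], size=pos.size
                )
                rate = np.clip(rate, 1e-3, None)
                amp = np.clip(
                    rng.normal(params.amplitude_mean, params.amplitude_sd, size=pos.size),
                    1e-3,
                    None,
                )
                k = 4.0 * rate
                c50 = ct + math.log(1.0 / CT_THRESHOLD_FRAC - 1.0) / k
                logistic = amp[:, None] / (
                    1.0 + np.exp(-k[:, None] * (cycles[None, :] - c50[:, None]))
                )
                intens[pos] += logistic
                ct_true[pos] = ct
            if params.noise_sd > 0:
                intens += rng.normal(0.0, params.noise_sd, size=intens.shape)

            blocks[(region, channel)] = TraceBlock(
                region=region,
                channel=channel,
                well_ids=np.arange(params.n_wells),
                cycles=cycles.copy(),
                intensities=intens,
            )
            truth_parts.append(
                pd.DataFrame(
                    {
                        "region": region,
                        "channel": channel,
                        "well_id": np.arange(params.n_wells),
                        "molecules": counts,
                        "ct_true": ct_true,
                        "lambda_true": lam,
                    }
                )
            )
    truth = pd.concat(truth_parts, ignore_index=True)
    return PlateRun(blocks=blocks), truth


# ---------------------------------------------------------------------------
# cohorts


# Blank-level signal (copies) for markers with no template: matched to
# typical no-template backgrounds of the assay, higher for the protein-oligo
# channels than for the transcript channels.
DEFAULT_BLANK_LAMBDA = {
    "EpCAM_protein": 100.0,
    "GPC3_protein": 100.0,
    "ASGPR_protein": 190.0,
    "EpCAM_mRNA": 8.0,
    "GPC3_mRNA": 9.0,
    "PDL1_mRNA": 5.0,
}


@dataclass(frozen=True)
class CohortDesign:
    """Clinical-style cohort generator: per-cohort, per-marker log-normal
    copy numbers with zero-inflation (dropout to blank-level background).

    ``distributions[cohort][marker] = (median_copies, sigma_log, dropout_p)``
    where copies ~ median * exp(sigma_log * Z) and with probability
    ``dropout_p`` the marker instead reads blank-level background drawn from
    a Poisson at the marker's no-template rate.
    """

    cohorts: tuple[tuple[str, int], ...]
    distributions: Mapping[str, Mapping[str, tuple[float, float, float]]]
    blank_lambda: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BLANK_LAMBDA))
    seed: int = 0

    def __post_init__(self) -> None:
        for label, n in self.cohorts:
            if n < 1:
                raise ValueError(f"cohort {label!r} must have n_samples >= 1")
            spec = self.distributions.get(label)
            if spec is None:
                raise ValueError(f"no distributions for cohort {label!r}")
            for marker, (med, sig, p) in spec.items():
                if marker not in MARKERS:
                    raise ValueError(f"unknown marker {marker!r}")
                if med < 0 or sig <= 0 or not (0.0 <= p <= 1.0):
                    raise ValueError(f"invalid distribution for {label}/{marker}")


def simulate_cohort(design: CohortDesign) -> pd.DataFrame:
    """Samples x markers copy matrix with cohort labels.

    Returns a DataFrame with columns ``sample_id, cohort, timepoint`` and
    the six marker columns; timepoint is "single" (treatment-pair shifting
    is applied downstream, in calibrated coordinates).
    """
    rng = np.random.default_rng([design.seed, 7])
    rows = []
    idx = 0
    for label, n in design.cohorts:
        spec = design.distributions[label]
        for _ in range(n):
            row: dict[str, object] = {
                "sample_id": f"{label}{idx:03d}",
                "cohort": label,
                "timepoint": "single",
            }
            for marker in MARKERS:
                med, sig, p_drop = spec.get(marker, (0.0, 1.0, 1.0))
                if med <= 0 or rng.random() < p_drop:
                    copies = float(rng.poisson(design.blank_lambda.get(marker, 0.0)))
                else:
                    copies = float(med * math.exp(sig * rng.standard_normal()))
                row[marker] = copies
            rows.append(row)
            idx += 1
    return pd.DataFrame(rows)


def default_cohort_design(
    n_healthy: int = 24, n_early: int = 31, n_advanced: int = 22, seed: int = 0
) -> CohortDesign:
    """Study-shaped default cohorts: healthy donors at blank-level signal,
    early-stage disease with moderate marker copies, intermediate-advanced
    disease with higher copies (cohort sizes default to the clinical-trial
    arms: 24 / 31 / 22).

    Marker medians rise faster than ASGPR across stages: more CTCs are
    captured in advanced disease *and* each expresses more EpCAM/GPC-3, so
    ASGPR-calibrated (per-cell) coordinates also shift outward with stage.
    """
    healthy = {m: (0.0, 1.0, 1.0) for m in MARKERS}  # all dropout -> blank
    early = {
        "EpCAM_protein": (450.0, 0.8, 0.25),
        "GPC3_protein": (250.0, 0.8, 0.35),
        "ASGPR_protein": (500.0, 0.7, 0.15),
        "EpCAM_mRNA": (150.0, 0.9, 0.25),
        "GPC3_mRNA": (100.0, 0.9, 0.35),
        "PDL1_mRNA": (60.0, 1.0, 0.45),
    }
    advanced = {
        "EpCAM_protein": (2500.0, 0.8, 0.10),
        "GPC3_protein": (1500.0, 0.8, 0.15),
        "ASGPR_protein": (900.0, 0.7, 0.05),
        "EpCAM_mRNA": (1000.0, 0.9, 0.10),
        "GPC3_mRNA": (700.0, 0.9, 0.15),
        "PDL1_mRNA": (350.0, 1.0, 0.25),
    }
    return CohortDesign(
        cohorts=(("HD", n_healthy), ("early_HCC", n_early), ("advanced_HCC", n_advanced)),
        distributions={"HD": healthy, "early_HCC": early, "advanced_HCC": advanced},
        seed=seed,
    )


def simulate_binormal_cohort(
    latent_auc: float,
    n_per_class: int,
    rho: float = 0.8,
    loc_log2: float = 8.0,
    scale_log2: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-cohort matrix whose equal-weight composite Z-score has a known
    latent (binormal) AUC.

    Each sample carries a latent severity t ~ N(delta * y, 1) (y = 0 for the
    healthy class, 1 for the disease class); each marker's log2(copies + 1)
    is ``loc + scale * (rho * t + sqrt(1 - rho^2) * eta)`` with independent
    eta. The equal-weight composite of per-marker z-scores is then itself
    binormal, and delta is solved so its AUC equals ``latent_auc``::

        AUC = Phi( rho * delta / sqrt(2 * (rho^2 + (1 - rho^2) / m)) )

    with m = 6 markers. Copies are 2**v - 1, so the log2(x+1) transform
    recovers v exactly and the latent AUC is preserved through scoring.
    """
    from scipy.stats import norm

    if not (0.5 < latent_auc < 1.0):
        raise ValueError("latent_auc must be in (0.5, 1)")
    if not (0.0 < rho <= 1.0):
        raise ValueError("rho must be in (0, 1]")
    m = len(MARKERS)
    sd_comp = math.sqrt(2.0 * (rho**2 + (1.0 - rho**2) / m))
    delta = norm.ppf(latent_auc) * sd_comp / rho
    rng = np.random.default_rng([seed, 11])
    rows = []
    for y, label in ((0, "HD"), (1, "HCC")):
        t = delta * y + rng.standard_normal(n_per_class)
        eta = rng.standard_normal((n_per_class, m))
        v = loc_log2 + scale_log2 * (rho * t[:, None] + math.sqrt(1.0 - rho**2) * eta)
        copies = np.maximum(np.exp2(v) - 1.0, 0.0)
        for i in range(n_per_class):
            row = {"sample_id": f"{label}{i:04d}", "cohort": label, "timepoint": "single"}
            row.update({mk: copies[i, j] for j, mk in enumerate(MARKERS)})
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dilution series


@dataclass(frozen=True)
class HitTable:
    """Detection outcomes of a dilution series: per concentration (CTC
    equivalents per mL), the number of replicates and how many detected."""

    concentrations: tuple[float, ...]
    n_replicates: tuple[int, ...]
    n_detected: tuple[int, ...]

    def __post_init__(self) -> None:
        if len({len(self.concentrations), len(self.n_replicates), len(self.n_detected)}) != 1:
            raise ValueError("ragged hit table")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be strictly positive")
        if len(set(self.concentrations)) != len(self.concentrations):
            raise ValueError("concentrations must be distinct")
        for n, d in zip(self.n_replicates, self.n_detected):
            if not (0 <= d <= n):
                raise ValueError("n_detected must lie in [0, n_replicates]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "concentration": self.concentrations,
                "n_replicates": self.n_replicates,
                "n_detected": self.n_detected,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HitTable":
        return cls(
            concentrations=tuple(float(c) for c in df["concentration"]),
            n_replicates=tuple(int(n) for n in df["n_replicates"]),
            n_detected=tuple(int(d) for d in df["n_detected"]),
        )


def simulate_dilution_series(
    concentrations: Sequence[float],
    reps: int,
    detect_model: tuple[float, float],
    seed: int = 0,
) -> HitTable:
    """Replicate detection outcomes under a probit dose-response model.

    ``detect_model = (a, b)`` gives detection probability
    Phi(a + b * log10(conc)); each row draws
    n_detected ~ Binomial(reps, p). Reproducible under the seed.
    """
    from scipy.stats import norm

    if reps < 1:
        raise ValueError("reps must be >= 1")
    concs = [float(c) for c in concentrations]
    if any(c <= 0 for c in concs):
        raise ValueError("concentrations must be strictly positive")
    a, b = detect_model
    rng = np.random.default_rng([seed, 13])
    p = norm.cdf(a + b * np.log10(concs))
    detected = rng.binomial(reps, p)
    return HitTable(
        concentrations=tuple(concs),
        n_replicates=tuple([reps] * len(concs)),
        n_detected=tuple(int(d) for d in detected),
    )
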