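"""Readers/writers, run configuration and the end-to-end pipeline.

The pipeline ties the stages together on one seeded synthetic dataset (or
user-supplied trace/cohort tables):

    simulate -> call -> quantify -> score -> profile -> report

Every artifact is a plain CSV or JSON file; a run manifest records the
tool version, a hash of the configuration, seeds and the checksum of every
output, so identical inputs and configuration reproduce byte-identical
output trees (the manifest deliberately carries no wall-clock timestamps).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .mpam import CallCriteria, PlateCalls, call_plate
from .panel import DEFAULT_PANEL, MARKERS, marker_for
from .profile import asgpr_calibrate, assign_regions, fit_region_classifier, region_proportions
from .quantify import poisson_quantify
from .score import score_cohort
from .simulate import PlateRun, PlateSimParams, default_cohort_design, simulate_cohort, simulate_plate

__all__ = [
    "PanelConfig",
    "RunManifest",
    "read_traces",
    "write_traces",
    "run_pipeline",
    "export_report",
]

log = logging.getLogger("dscout")

TRACE_COLUMNS = ["region", "well_id", "channel", "cycle", "intensity"]


@dataclass(frozen=True)
class PanelConfig:
    """Configuration of a full run.

    ``target_copies`` uses "region:channel" string keys in JSON form.
    ``marker_map`` must map every (region, channel) pair to a unique
    marker; the default is the standard six-marker panel.
    """

    n_wells: int = 20000
    n_cycles: int = 40
    target_copies: Mapping[str, float] = field(
        default_factory=lambda: {
            "protein:FAM": 500.0,
            "protein:VIC": 250.0,
            "protein:CY5": 450.0,
            "mrna:FAM": 200.0,
            "mrna:VIC": 120.0,
            "mrna:CY5": 80.0,
        }
    )
    marker_map: Mapping[str, str] = field(
        default_factory=lambda: {f"{r}:{c}": m for (r, c), m in DEFAULT_PANEL.items()}
    )
    noise_sd: float = 0.02
    criteria: Mapping[str, Any] = field(default_factory=dict)
    reference: str = "all"
    kernel: str = "poly"
    ahp_matrix: list[list[float]] | None = None
    cohort_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"HD": 24, "early_HCC": 31, "advanced_HCC": 22}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        markers = list(self.marker_map.values())
        if len(set(markers)) != len(markers):
            raise ValueError("marker_map must map each (region, channel) to a unique marker")
        missing = [m for m in MARKERS if m not in markers]
        if missing:
            raise ValueError(f"marker_map missing markers: {missing}")
        for key in self.target_copies:
            if key not in self.marker_map:
                raise ValueError(f"target_copies key {key!r} has no marker mapping")

    @classmethod
    def from_json(cls, path: str | Path) -> "PanelConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["target_copies"] = dict(d["target_copies"])
        d["marker_map"] = dict(d["marker_map"])
        d["criteria"] = dict(d["criteria"])
        d["cohort_sizes"] = dict(d["cohort_sizes"])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def sim_params(self) -> PlateSimParams:
        tc = {tuple(k.split(":")): float(v) for k, v in self.target_copies.items()}
        return PlateSimParams(
            n_wells=self.n_wells,
            n_cycles=self.n_cycles,
            target_copies=tc,
            noise_sd=self.noise_sd,
            seed=self.seed,
        )

    def call_criteria(self) -> CallCriteria:
        kw = dict(self.criteria)
        if "ct_window" in kw:
            kw["ct_window"] = tuple(kw["ct_window"])
        return CallCriteria(**kw)


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    outputs: dict[str, str]  # relative path -> sha256

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# table readers/writers


def read_traces(path: str | Path) -> PlateRun:
    """Read a long-format trace CSV (``region,well_id,channel,cycle,intensity``).

    Validates the header, rejects duplicate (region, well, channel, cycle)
    rows and ragged cycle coverage, and returns traces sorted by cycle.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if not pd.api.types.is_numeric_dtype(df["intensity"]):
        raise ValueError(f"{path}: non-numeric intensity column")
    return PlateRun.from_frame(df)


def write_traces(run: PlateRun, path: str | Path) -> None:
    run.to_frame().to_csv(path, index=False, float_format="%.6f")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def quantify_calls(calls: PlateCalls, marker_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Poisson copies per (region, channel) from plate-call summaries."""
    rows = []
    for _, r in calls.summary.iterrows():
        region, channel = r["region"], r["channel"]
        key = f"{region}:{channel}"
        marker = (
            marker_map[key] if marker_map and key in marker_map else marker_for(region, channel)
        )
        q = poisson_quantify(int(r["M"]), int(r["N"]))
        rows.append(
            {
                "region": region,
                "channel": channel,
                "marker": marker,
                "M": q.M,
                "N": q.N,
                "copies": q.X,
                "ci_low": q.ci_low,
                "ci_high": q.ci_high,
                "saturated": q.saturated,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _write_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(
    config: PanelConfig,
    out_dir: str | Path,
    traces: PlateRun | None = None,
    cohort: pd.DataFrame | None = None,
    dry_run: bool = False,
) -> RunManifest | list[str]:
    """Execute simulate -> call -> quantify -> score -> profile -> report.

    With ``traces``/``cohort`` given they replace the simulated inputs.
    ``dry_run`` returns the stage plan without touching the filesystem.
    Outputs land in ``out_dir``; the returned manifest lists their
    checksums and is itself written as ``manifest.json``.
    """
    stages = ["simulate", "call", "quantify", "score", "profile", "report"]
    if dry_run:
        return stages
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    def _stage(name: str) -> None:
        log.info("stage %-8s done at %.2fs", name, time.perf_counter() - t0)

    # simulate (or ingest)
    truth = None
    if traces is None:
        traces, truth = simulate_plate(config.sim_params())
        _write_csv(
            truth[["region", "channel", "well_id", "molecules", "ct_true"]],
            out / "truth.csv",
        )
    write_traces(traces, out / "traces.csv")
    if cohort is None:
        sizes = config.cohort_sizes
        cohort = simulate_cohort(
            default_cohort_design(
                n_healthy=sizes.get("HD", 24),
                n_early=sizes.get("early_HCC", 31),
                n_advanced=sizes.get("advanced_HCC", 22),
                seed=config.seed,
            )
        )
    _write_csv(cohort, out / "cohort.csv")
    _stage("simulate")

    # call
    calls = call_plate(traces, config.call_criteria())
    _write_csv(calls.calls, out / "calls.csv")
    _write_csv(calls.summary, out / "plate_summary.csv")
    _stage("call")

    # quantify
    quant = quantify_calls(calls, config.marker_map)
    _write_csv(quant, out / "quant.csv")
    _stage("quantify")

    # score
    weights = None
    if config.ahp_matrix is not None:
        from .score import ahp_weights

        cols = [m for m in MARKERS if m in cohort.columns]
        w, _cr = ahp_weights(np.asarray(config.ahp_matrix, float))
        weights = pd.Series(w, index=cols)
    result = score_cohort(cohort, weights=weights, reference=config.reference)
    scores = cohort[["sample_id", "cohort"]].copy()
    for m in result.z.columns:
        scores[f"z_{m}"] = result.z[m].to_numpy()
    scores["composite"] = result.composite.to_numpy()
    _write_csv(scores, out / "scores.csv")
    _write_json(
        {
            "weights": {m: float(w) for m, w in result.weights.items()},
            "reference": result.reference,
            "warnings": list(result.warnings),
        },
        out / "weights.json",
    )
    _stage("score")

    # profile
    points = asgpr_calibrate(cohort)
    healthy = "HD" if (cohort["cohort"] == "HD").any() else str(cohort["cohort"].iloc[0])
    prof_meta: dict[str, Any] = {}
    region_rows = []
    prop_rows = []
    for marker, g in points.groupby("marker", sort=True):
        binary = np.where(g["cohort"] == healthy, healthy, "HCC")
        if len(set(binary)) < 2 or min((binary == healthy).sum(), (binary != healthy).sum()) < 3:
            prof_meta[marker] = {"skipped": "need both cohorts with >= 3 samples"}
            continue
        model = fit_region_classifier(
            g[["x", "y"]].to_numpy(), binary, kernel=config.kernel, seed=config.seed,
            healthy_label=healthy,
        )
        regions = assign_regions(g[["x", "y"]].to_numpy(), model)
        region_rows.append(
            pd.DataFrame(
                {"sample_id": g["sample_id"], "marker": marker, "region": regions}
            )
        )
        props = region_proportions(regions, g["cohort"])
        props.insert(0, "marker", marker)
        prop_rows.append(props)
        prof_meta[marker] = {
            "kernel": model.kernel,
            "train_accuracy": model.train_accuracy,
            **model.cv_metrics,
        }
    if region_rows:
        _write_csv(pd.concat(region_rows, ignore_index=True), out / "regions.csv")
        _write_csv(pd.concat(prop_rows, ignore_index=True), out / "region_proportions.csv")
    _write_json(prof_meta, out / "classifier_metrics.json")
    _stage("profile")

    # report + manifest
    export_report(out)
    _stage("report")
    outputs = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.suffix in {".csv", ".json"} and p.name != "manifest.json"
    }
    manifest = RunManifest(
        version=__version__, config_hash=config.config_hash(), seed=config.seed, outputs=outputs
    )
    _write_json(manifest.to_dict(), out / "manifest.json")
    return manifest


def export_report(out_dir: str | Path) -> Path:
    """Machine-readable JSON summary of a completed run directory."""
    out = Path(out_dir)
    report: dict[str, Any] = {"notice": None}
    quant_path = out / "quant.csv"
    if quant_path.exists():
        quant = pd.read_csv(quant_path)
        report["copies_per_marker"] = {
            str(r["marker"]): float(r["copies"]) for _, r in quant.iterrows()
        }
    scores_path = out / "scores.csv"
    if scores_path.exists():
        scores = pd.read_csv(scores_path)
        if scores.empty:
            report["notice"] = "zero samples in cohort"
        else:
            report["composite_score_by_cohort"] = {
                str(c): float(v)
                for c, v in scores.groupby("cohort")["composite"].mean().items()
            }
            report["n_samples"] = int(len(scores))
    props_path = out / "region_proportions.csv"
    if props_path.exists():
        props = pd.read_csv(props_path)
        report["p2_fraction"] = {
            f"{r['marker']}/{r['cohort']}": float(r["P2"]) for _, r in props.iterrows()
        }
    path = out / "report.json"
    _write_json(report, path)
    return path


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(stream=sys.stderr, level=getattr(logging, level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
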