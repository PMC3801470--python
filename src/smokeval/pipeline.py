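"""End-to-end orchestration: simulate -> qc -> assign -> evaluate -> model.

Each stage writes plain-text artifacts into the output directory; a manifest
records the full parameterization, seed, package version and a checksum of
every artifact, so a rerun with identical configuration is bit-identical for
all deterministic outputs (timings go to run.log only).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ScenarioConfig
from .datatypes import Scenario
from .exposure import build_exposure_table, derive_forecast_plume, \
    grid_value_at_points
from .health import run_health_models
from .io import write_grids, write_plumes, write_region_map, write_table
from .qc import apply_pressure_filter, daily_averages
from .simulate import simulate_scenario
from .verification import bland_altman, evaluate, fms

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineState", "run_pipeline", "STAGES"]

STAGES = ("simulate", "qc", "assign", "evaluate", "model")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    outdir: str | Path = "smokeval_run"
    stages: tuple[str, ...] = STAGES
    nrmse_normalizer: str = "range"
    coverage_threshold: float = 0.5
    truncation_cap: float = 300.0
    stratify_threshold: "int | str" = "mean"

    def __post_init__(self) -> None:
        for i, s in enumerate(self.stages):
            if s != STAGES[i]:
                raise ValueError(
                    f"stages must form a prefix of {STAGES}, got {self.stages}")


@dataclass
class PipelineState:
    """In-memory results of the stages that have run."""

    scenario: Scenario | None = None
    daily_monitor: pd.DataFrame | None = None
    exposures: pd.DataFrame | None = None
    evaluation: dict | None = None
    model_results: pd.DataFrame | None = None
    artifacts: list[Path] = field(default_factory=list)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))


def _stage_simulate(cfg: RunConfig, out: Path, state: PipelineState) -> None:
    sc = simulate_scenario(cfg.scenario)
    state.scenario = sc
    write_region_map(sc.region, out / "region")
    write_grids(sc.grids, out / "forecast_grid.csv")
    write_plumes(sc.forecast_plumes, out / "plumes_forecast.geojson")
    write_plumes(sc.observed_plumes, out / "plumes_observed.geojson")
    write_table(sc.hourly_obs, out / "monitor_hourly.csv")
    write_table(sc.temperature, out / "temperature.csv")
    write_table(sc.health_panel, out / "health_panel.csv")
    _write_json({"true_betas": sc.truth.true_betas,
                 "true_area_intercepts": sc.truth.true_area_intercepts},
                out / "truth.json")
    state.artifacts += [out / n for n in (
        "forecast_grid.csv", "plumes_forecast.geojson", "plumes_observed.geojson",
        "monitor_hourly.csv", "temperature.csv", "health_panel.csv", "truth.json")]


def _stage_qc(cfg: RunConfig, out: Path, state: PipelineState) -> None:
    hourly = apply_pressure_filter(state.scenario.hourly_obs)
    daily = daily_averages(hourly)
    state.daily_monitor = daily
    write_table(daily, out / "monitor_daily.csv")
    state.artifacts.append(out / "monitor_daily.csv")


def _stage_assign(cfg: RunConfig, out: Path, state: PipelineState) -> None:
    sc = state.scenario
    days = list(range(1, cfg.scenario.n_days + 1))
    table = build_exposure_table(
        sc.region, sc.grids, sc.forecast_plumes, sc.observed_plumes,
        state.daily_monitor, days, cfg.scenario.dates(),
        coverage_threshold=cfg.coverage_threshold)
    state.exposures = table
    write_table(table, out / "exposure_table.csv")
    state.artifacts.append(out / "exposure_table.csv")


def build_paired_series(scenario: Scenario,
                        daily_monitor: pd.DataFrame) -> pd.DataFrame:
    """Monitor-day pairs: QC'd daily observation vs co-located forecast.

    Pairs exist only where the day's forecast is available and the monitor's
    QC'd daily value is non-missing.
    """
    mons = scenario.region.monitors
    dates = scenario.config.dates()
    rows = []
    for day in range(1, scenario.config.n_days + 1):
        grid = scenario.grids[day]
        if not grid.available:
            continue
        f = grid_value_at_points(grid, mons["x_km"].to_numpy(),
                                 mons["y_km"].to_numpy())
        date = dates[day - 1]
        dv = daily_monitor[daily_monitor["date"] == date]
        dv = dv.dropna(subset=["value"]).set_index("monitor_id")["value"]
        for k, mid in enumerate(mons["monitor_id"]):
            if mid in dv.index:
                rows.append((mid, day, float(dv[mid]), float(f[k])))
    return pd.DataFrame(rows, columns=["location_id", "day", "observed",
                                       "forecast"])


def _stage_evaluate(cfg: RunConfig, out: Path, state: PipelineState) -> None:
    sc = state.scenario
    pairs = build_paired_series(sc, state.daily_monitor)
    norm = cfg.nrmse_normalizer
    glob = evaluate(pairs, "global", norm).global_stats
    spatial = evaluate(pairs, "spatial", norm)
    temporal = evaluate(pairs, "temporal", norm)
    try:
        ba = bland_altman(pairs)
        ba_summary = {"bias": ba.bias, "limits": list(ba.limits),
                      "n_pairs": int(ba.differences.size)}
    except ValueError:
        ba_summary = None

    fms_rows = []
    for day in sorted(sc.forecast_plumes):
        if not sc.grids[day].available:
            continue
        v = fms(sc.forecast_plumes[day], sc.observed_plumes[day])
        fms_rows.append((day, v))
    fms_df = pd.DataFrame(fms_rows, columns=["day", "fms"])
    fms_valid = fms_df["fms"].dropna()

    report = {
        "normalizer": norm,
        "global": dataclasses.asdict(glob),
        "spatial": {k: list(v) for k, v in spatial.mean_and_range().items()},
        "temporal": {k: list(v) for k, v in temporal.mean_and_range().items()},
        "bland_altman": ba_summary,
        "fms_mean": float(fms_valid.mean()) if len(fms_valid) else math.nan,
        "fms_range": ([float(fms_valid.min()), float(fms_valid.max())]
                      if len(fms_valid) else None),
        "n_fms_days": int(len(fms_valid)),
    }
    state.evaluation = report
    _write_json(report, out / "evaluation_report.json")
    write_table(spatial.slices, out / "evaluation_spatial.csv")
    write_table(temporal.slices, out / "evaluation_temporal.csv")
    write_table(fms_df, out / "fms_daily.csv")
    write_table(pairs, out / "paired_series.csv")
    state.artifacts += [out / n for n in (
        "evaluation_report.json", "evaluation_spatial.csv",
        "evaluation_temporal.csv", "fms_daily.csv", "paired_series.csv")]


def _stage_model(cfg: RunConfig, out: Path, state: PipelineState) -> None:
    results = run_health_models(
        state.scenario.health_panel, state.exposures,
        stratify=True, stratify_threshold=cfg.stratify_threshold)
    state.model_results = results
    write_table(results, out / "model_results.csv")
    _write_json(results.to_dict(orient="records"), out / "model_results.json")
    state.artifacts += [out / "model_results.csv", out / "model_results.json"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "assign": _stage_assign,
    "evaluate": _stage_evaluate,
    "model": _stage_model,
}


def run_pipeline(cfg: RunConfig) -> PipelineState:
    """Execute the configured stage prefix and write a manifest.

    A stage failure raises with the failing stage named; artifacts written by
    earlier stages are retained.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    state = PipelineState()
    timings = {}
    for stage in cfg.stages:
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](cfg, out, state)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        timings[stage] = time.perf_counter() - t0
        logger.info("stage %s done in %.2f s", stage, timings[stage])

    manifest = {
        "package": "smokeval",
        "version": __version__,
        "seed": cfg.scenario.seed,
        "stages": list(cfg.stages),
        "scenario": cfg.scenario.to_dict(),
        "options": {
            "nrmse_normalizer": cfg.nrmse_normalizer,
            "coverage_threshold": cfg.coverage_threshold,
            "truncation_cap": cfg.truncation_cap,
            "stratify_threshold": cfg.stratify_threshold,
        },
        "artifacts": {p.name: _sha256(p) for p in state.artifacts},
    }
    _write_json(manifest, out / "manifest.json")
    (out / "run.log").write_text(
        "".join(f"{s}\t{t:.3f}s\n" for s, t in timings.items()))
    return state


def demo_run(outdir: str | Path, seed: int = 0,
             stages: tuple[str, ...] = STAGES) -> PipelineState:
    """Run the default 89-area, 35-day scenario end to end."""
    cfg = RunConfig(scenario=ScenarioConfig(seed=seed), outdir=outdir,
                    stages=stages)
    return run_pipeline(cfg)
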