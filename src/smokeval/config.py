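"""Scenario configuration for the synthetic smoke-forecast study.

The default configuration reproduces the structure of a 35-day provincial
wildfire-smoke episode: 89 local health areas (LHAs) tiling a 600 km square
domain, 3-474 census dissemination-area (DA) centroids per LHA with 400-700
persons each, 36 PM2.5 monitors, a zero-inflated right-skewed forecast field
(pooled mean ~4 ug/m3, SD ~27 ug/m3, ~60% zeros), and two health indicators
with known injectable rate ratios per 30 ug/m3 of lag 0-1 exposure.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

__all__ = ["OutcomeConfig", "ScenarioConfig", "load_config"]


@dataclass(frozen=True)
class OutcomeConfig:
    """Generative parameters for one daily health indicator.

    Parameters
    ----------
    true_rr_per_30 : float
        Rate ratio per 30 ug/m3 of lag 0-1 population-weighted forecast PM2.5.
    baseline_rate_range : (float, float)
        Per-area weekday baseline rates, events per 100,000 person-days;
        drawn log-uniformly within this range.
    weekend_rate_multiplier : float
        Multiplicative rate change on weekends and holidays.
    n_areas_with_data : int or None
        Number of areas reporting this outcome (None = all areas).
    """

    true_rr_per_30: float = 1.08
    baseline_rate_range: tuple[float, float] = (17.7, 72.2)
    weekend_rate_multiplier: float = 0.42
    n_areas_with_data: int | None = 85

    def __post_init__(self) -> None:
        lo, hi = self.baseline_rate_range
        if not (0 < lo < hi):
            raise ValueError("baseline_rate_range must satisfy 0 < low < high")
        if self.true_rr_per_30 <= 0:
            raise ValueError("true_rr_per_30 must be positive")
        if self.weekend_rate_multiplier <= 0:
            raise ValueError("weekend_rate_multiplier must be positive")

    @property
    def beta_per_ugm3(self) -> float:
        """Log-rate slope per ug/m3 implied by the configured RR per 30."""
        return math.log(self.true_rr_per_30) / 30.0


def _default_outcomes() -> dict[str, OutcomeConfig]:
    return {
        "dispensations": OutcomeConfig(
            true_rr_per_30=1.08,
            baseline_rate_range=(17.7, 72.2),
            weekend_rate_multiplier=0.42,
            n_areas_with_data=85,
        ),
        "physician_visits": OutcomeConfig(
            true_rr_per_30=1.05,
            baseline_rate_range=(2.7, 21.1),
            weekend_rate_multiplier=0.32,
            n_areas_with_data=73,
        ),
    }


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterization of a synthetic study scenario.

    All lengths are planar kilometres; concentrations are ug/m3.
    """

    # -- study dimensions ---------------------------------------------------
    n_areas: int = 89
    n_days: int = 35
    n_monitors: int = 36
    das_per_area_range: tuple[int, int] = (3, 474)
    da_pop_range: tuple[int, int] = (400, 700)
    domain_km: float = 600.0
    grid_cell_km: float = 10.0
    start_date: _dt.date = _dt.date(2010, 7, 5)  # a Monday
    holiday_days: tuple[int, ...] = (29,)  # civic holiday in week 5

    # -- forecast field -----------------------------------------------------
    # Marginal cell distribution: zero w.p. forecast_zero_prob; otherwise a
    # contiguous smoke blob whose core cells (episode_cell_prob of the domain)
    # carry heavy episode concentrations and whose halo carries trace "haze".
    forecast_zero_prob: float = 0.60
    forecast_lognorm_params: tuple[float, float] = (math.log(0.03), 1.0)
    episode_cell_prob: float = 0.03
    episode_lognorm_params: tuple[float, float] = (4.71, 0.60)
    n_episodes: int = 2
    n_missing_forecast_days: int = 2

    # -- observed (satellite-analogue) plumes --------------------------------
    plume_shift_km: float = 230.0
    plume_dilation_km: float = 30.0

    # -- monitors ------------------------------------------------------------
    agreement_coupling: float = 0.5
    obs_background_mean: float = 8.0
    obs_noise_sd: float = 4.0
    hourly_jitter: float = 0.3
    pressure_exceed_prob: float = 0.01
    hourly_missing_prob: float = 0.01
    consecutive_missing_prob: float = 0.02

    # -- temperature ---------------------------------------------------------
    temp_base_c: float = 25.0
    temp_amplitude_c: float = 6.0
    temp_noise_sd_c: float = 1.5

    # -- health outcomes -----------------------------------------------------
    outcomes: dict[str, OutcomeConfig] = field(default_factory=_default_outcomes)
    temperature_effect_per_degc: float = 0.01
    overdispersion_sd: float = 0.05

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_areas", "n_days", "n_monitors", "n_episodes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("forecast_zero_prob", "episode_cell_prob",
                     "pressure_exceed_prob", "hourly_missing_prob",
                     "consecutive_missing_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0.0 <= self.agreement_coupling <= 1.0):
            raise ValueError("agreement_coupling must lie in [0, 1]")
        lo, hi = self.das_per_area_range
        if not (1 <= lo <= hi):
            raise ValueError("das_per_area_range must satisfy 1 <= low <= high")
        lo, hi = self.da_pop_range
        if not (1 <= lo <= hi):
            raise ValueError("da_pop_range must satisfy 1 <= low <= high")
        if self.domain_km <= 0 or self.grid_cell_km <= 0:
            raise ValueError("domain_km and grid_cell_km must be positive")
        n_cells_side = self.domain_km / self.grid_cell_km
        if abs(n_cells_side - round(n_cells_side)) > 1e-9:
            raise ValueError("domain_km must be an integer multiple of grid_cell_km")
        if self.n_missing_forecast_days >= self.n_days:
            raise ValueError("n_missing_forecast_days must be < n_days")
        if not (0.0 <= self.hourly_jitter < 0.5):
            raise ValueError("hourly_jitter must lie in [0, 0.5)")
        if self.overdispersion_sd < 0 or self.obs_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        for name, oc in self.outcomes.items():
            if oc.n_areas_with_data is not None and not (
                1 <= oc.n_areas_with_data <= self.n_areas
            ):
                raise ValueError(f"outcome {name!r}: n_areas_with_data out of range")

    # -- derived -------------------------------------------------------------
    @property
    def n_cells_side(self) -> int:
        return round(self.domain_km / self.grid_cell_km)

    def dates(self) -> list[_dt.date]:
        """Calendar dates of study days 1..n_days."""
        return [self.start_date + _dt.timedelta(days=d) for d in range(self.n_days)]

    def rng_streams(self) -> dict[str, np.random.Generator]:
        """Named, independent substreams spawned from the master seed."""
        names = ["region", "smoke", "missing_days", "plume_mismatch",
                 "monitors", "temperature", "health"]
        seqs = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(s) for n, s in zip(names, seqs)}

    # -- (de)serialisation ----------------------------------------------------
    def replace(self, **changes: Any) -> "ScenarioConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["start_date"] = self.start_date.isoformat()
        d["holiday_days"] = list(self.holiday_days)
        for k in ("das_per_area_range", "da_pop_range",
                  "forecast_lognorm_params", "episode_lognorm_params"):
            d[k] = list(d[k])
        d["outcomes"] = {
            name: {**dataclasses.asdict(oc),
                   "baseline_rate_range": list(oc.baseline_rate_range)}
            for name, oc in self.outcomes.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ScenarioConfig":
        d = dict(d)
        if "start_date" in d and isinstance(d["start_date"], str):
            d["start_date"] = _dt.date.fromisoformat(d["start_date"])
        for k in ("das_per_area_range", "da_pop_range", "holiday_days",
                  "forecast_lognorm_params", "episode_lognorm_params"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        if "outcomes" in d:
            d["outcomes"] = {
                name: oc if isinstance(oc, OutcomeConfig) else OutcomeConfig(
                    **{**oc, "baseline_rate_range": tuple(oc["baseline_rate_range"])}
                )
                for name, oc in d["outcomes"].items()
            }
        return cls(**d)


def load_config(path: str | Path) -> ScenarioConfig:
    """Load a ScenarioConfig from a YAML or JSON file."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} did not parse to a mapping")
    return ScenarioConfig.from_dict(data)


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    """Write a ScenarioConfig to YAML (or JSON by extension)."""
    d = config.to_dict()
    p = Path(path)
    if p.suffix == ".json":
        p.write_text(json.dumps(d, indent=2, sort_keys=True))
    else:
        p.write_text(yaml.safe_dump(d, sort_keys=True))
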