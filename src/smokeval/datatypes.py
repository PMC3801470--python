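"""Core in-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from shapely.geometry.base import BaseGeometry

__all__ = ["RegionMap", "GridForecast", "PlumeSet", "TruthRecord", "Scenario"]


@dataclass
class RegionMap:
    """Planar (km-unit) study geography.

    Attributes
    ----------
    areas : list of (area_id, shapely Polygon)
        Health areas tiling a rectangular domain.
    population_points : DataFrame with columns
        point_id, area_id, x_km, y_km, population.
        Census-unit centroids carrying the population weights.
    monitors : DataFrame with columns monitor_id, x_km, y_km.
    """

    areas: list[tuple[str, Polygon]]
    population_points: pd.DataFrame
    monitors: pd.DataFrame

    @property
    def area_ids(self) -> list[str]:
        return [a for a, _ in self.areas]

    def area_polygon(self, area_id: str) -> Polygon:
        for a, poly in self.areas:
            if a == area_id:
                return poly
        raise KeyError(area_id)

    def area_centroids(self) -> pd.DataFrame:
        rows = [(a, p.centroid.x, p.centroid.y) for a, p in self.areas]
        return pd.DataFrame(rows, columns=["area_id", "x_km", "y_km"])

    def total_population(self) -> int:
        return int(self.population_points["population"].sum())


@dataclass
class GridForecast:
    """One day's forecast surface on an axis-aligned cell grid.

    Cell (i, j) covers the half-open box
    [x0 + j*c, x0 + (j+1)*c) x [y0 + i*c, y0 + (i+1)*c), c = cell_km.
    ``available=False`` marks a day whose forecast is treated as missing by
    downstream stages (the field itself is still defined for truth purposes).
    """

    day: int
    x0_km: float
    y0_km: float
    cell_km: float
    values: np.ndarray  # shape (n_rows, n_cols), >= 0
    available: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be a 2-D matrix")
        if np.any(self.values < 0):
            raise ValueError("grid values must be non-negative")
        if self.cell_km <= 0:
            raise ValueError("cell size must be positive")


@dataclass
class PlumeSet:
    """Daily set of smoke-plume polygons from one source."""

    day: int
    polygons: list[BaseGeometry]
    source: str  # "forecast_derived" or "observed"
    _union_cache: BaseGeometry | None = field(
        default=None, repr=False, compare=False)

    def union(self) -> BaseGeometry:
        from shapely.ops import unary_union

        if self._union_cache is None:
            self._union_cache = (
                Polygon() if not self.polygons else unary_union(self.polygons)
            )
        return self._union_cache

    @property
    def area(self) -> float:
        return float(self.union().area)

    def is_empty(self) -> bool:
        return len(self.polygons) == 0 or self.union().is_empty


@dataclass
class TruthRecord:
    """Ground truth of a simulated scenario, for parameter-recovery checks.

    ``true_betas`` holds log-rate coefficients per outcome, including the
    exposure slope per ug/m3; ``true_area_intercepts`` holds per-area weekday
    log baseline rates (per person-day); ``realized_exposures`` is the full
    (no-missing) per-area-day exposure table used to generate counts.
    """

    true_betas: dict[str, dict[str, float]]
    true_area_intercepts: dict[str, dict[str, float]]
    realized_exposures: pd.DataFrame


@dataclass
class Scenario:
    """A complete simulated study: geography, fields, observations, outcomes."""

    config: "ScenarioConfig"  # noqa: F821 - forward ref, avoids import cycle
    region: RegionMap
    grids: dict[int, GridForecast]
    forecast_plumes: dict[int, PlumeSet]
    observed_plumes: dict[int, PlumeSet]
    hourly_obs: pd.DataFrame
    temperature: pd.DataFrame  # monitor_id, day, tmax_c
    health_panel: pd.DataFrame | None = None
    truth: TruthRecord | None = None
    extras: dict = field(default_factory=dict)
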