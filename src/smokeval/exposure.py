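"""Exposure assignment: area-day smoke exposures from grids, monitors, plumes.

Four exposures are assigned to each health area and day: the
population-weighted forecast PM2.5 at census-unit centroids, the
population-weighted PM2.5 of the nearest valid monitor, and two binary flags
marking whether more than half the area's population lies under the
forecast-derived or the observed smoke plume. Lag 0-1 versions average
(continuous) or OR-combine (binary) the same and previous day.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box
from shapely.ops import unary_union

from .datatypes import GridForecast, PlumeSet, RegionMap

logger = logging.getLogger(__name__)

__all__ = [
    "grid_value_at_points", "nearest_monitor_values", "population_weighted_mean",
    "plume_coverage_flag", "derive_forecast_plume", "daily_plume_union",
    "lag01", "build_exposure_table",
]


def grid_value_at_points(grid: GridForecast, x_km, y_km) -> np.ndarray:
    """Value of the grid cell containing each point; 0 outside the grid.

    Cells are half-open boxes [x_min, x_max) x [y_min, y_max), so a point on a
    shared edge belongs to the cell on the increasing side. Points outside the
    grid extent receive 0: beyond the model domain no smoke is forecast.
    """
    x = np.asarray(x_km, dtype=float)
    y = np.asarray(y_km, dtype=float)
    nrows, ncols = grid.values.shape
    col = np.floor((x - grid.x0_km) / grid.cell_km).astype(int)
    row = np.floor((y - grid.y0_km) / grid.cell_km).astype(int)
    inside = (col >= 0) & (col < ncols) & (row >= 0) & (row < nrows)
    out = np.zeros(x.shape, dtype=float)
    out[inside] = grid.values[row[inside], col[inside]]
    return out


def nearest_monitor_values(
    daily: pd.DataFrame, monitors: pd.DataFrame, x_km, y_km, date
) -> np.ndarray:
    """Value of the nearest monitor with a non-missing value on ``date``.

    Parameters
    ----------
    daily : DataFrame
        QC'd daily table (monitor_id, date, value) as produced by
        :func:`smokeval.qc.daily_averages`.
    monitors : DataFrame
        monitor_id, x_km, y_km. Distance is planar Euclidean; ties are broken
        by lexicographic monitor_id.

    Returns
    -------
    ndarray of values (NaN for every point if all monitors are missing).
    """
    x = np.asarray(x_km, dtype=float)
    y = np.asarray(y_km, dtype=float)
    day_vals = daily[daily["date"] == date].dropna(subset=["value"])
    if day_vals.empty:
        return np.full(x.shape, np.nan)
    # deterministic tie-break: sort by monitor_id, argmin keeps first minimum
    mon = monitors.merge(day_vals[["monitor_id", "value"]], on="monitor_id")
    mon = mon.sort_values("monitor_id", kind="stable").reset_index(drop=True)
    dx = x[:, None] - mon["x_km"].to_numpy()[None, :]
    dy = y[:, None] - mon["y_km"].to_numpy()[None, :]
    idx = np.argmin(dx * dx + dy * dy, axis=1)
    return mon["value"].to_numpy()[idx]


def population_weighted_mean(values, populations) -> float:
    """Population-weighted mean, excluding missing values pairwise.

    Returns NaN if every value is missing or the input is empty.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(populations, dtype=float)
    if v.shape != w.shape:
        raise ValueError("values and populations must have equal length")
    if v.size == 0:
        return math.nan
    if np.any(w <= 0) or np.isnan(w).any():
        raise ValueError("populations must be positive")
    ok = ~np.isnan(v)
    if not ok.any():
        return math.nan
    return float(np.sum(v[ok] * w[ok]) / np.sum(w[ok]))


def plume_coverage_flag(
    plumes: PlumeSet, x_km, y_km, populations, threshold: float = 0.5
) -> int:
    """1 iff strictly more than ``threshold`` of the population is under plume.

    Points on a plume boundary count as covered (closed-set membership keeps
    the flag monotone under plume dilation).
    """
    x = np.asarray(x_km, dtype=float)
    y = np.asarray(y_km, dtype=float)
    w = np.asarray(populations, dtype=float)
    if x.size == 0:
        raise ValueError("area must contain at least one population point")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    if plumes.is_empty():
        return 0
    union = plumes.union()
    pts = shapely.points(x, y)
    covered = shapely.intersects(union, pts)  # boundary-inclusive
    frac = float(np.sum(w[covered]) / np.sum(w))
    return int(frac > threshold)


def derive_forecast_plume(grid: GridForecast) -> PlumeSet:
    """Plume outline of a forecast grid: union of all cells with value > 0.

    Edge-adjacent positive cells merge into maximal polygons; an all-zero
    grid yields an empty plume set. Total polygon area equals the cell area
    times the number of positive cells exactly.
    """
    rows, cols = np.nonzero(grid.values > 0.0)
    if rows.size == 0:
        return PlumeSet(day=grid.day, polygons=[], source="forecast_derived")
    c = grid.cell_km
    boxes = [
        box(grid.x0_km + j * c, grid.y0_km + i * c,
            grid.x0_km + (j + 1) * c, grid.y0_km + (i + 1) * c)
        for i, j in zip(rows, cols)
    ]
    merged = unary_union(boxes)
    polys = list(merged.geoms) if merged.geom_type == "MultiPolygon" else [merged]
    return PlumeSet(day=grid.day, polygons=polys, source="forecast_derived")


def daily_plume_union(sub_daily: list[PlumeSet]) -> PlumeSet:
    """Union of same-day plume sets (density categories discarded)."""
    if not sub_daily:
        raise ValueError("need at least one plume set")
    days = {p.day for p in sub_daily}
    if len(days) > 1:
        raise ValueError("plume sets must share a day")
    polys = [g for p in sub_daily for g in p.polygons]
    if not polys:
        return PlumeSet(day=sub_daily[0].day, polygons=[], source=sub_daily[0].source)
    merged = unary_union(polys)
    out = list(merged.geoms) if merged.geom_type == "MultiPolygon" else [merged]
    return PlumeSet(day=sub_daily[0].day, polygons=out, source=sub_daily[0].source)


def lag01(series, kind: str = "continuous") -> np.ndarray:
    """Lag 0-1 exposure over consecutive days.

    Continuous: mean of same-day and previous-day values; binary: 1 if either
    day is 1. The first day (and any day whose previous value is missing)
    falls back to the same-day value; a missing same-day value stays missing.
    """
    v = np.asarray(series, dtype=float)
    if v.ndim != 1:
        raise ValueError("series must be 1-D over consecutive days")
    out = v.copy()
    if v.size >= 2:
        prev = v[:-1]
        cur = v[1:]
        if kind == "continuous":
            comb = np.where(np.isnan(prev), cur, (cur + prev) / 2.0)
        elif kind == "binary":
            comb = np.where(np.isnan(prev), cur, np.fmax(cur, prev))
        else:
            raise ValueError(f"unknown kind {kind!r}")
        out[1:] = np.where(np.isnan(cur), np.nan, comb)
    return out


def build_exposure_table(
    region: RegionMap,
    grids: dict[int, GridForecast],
    forecast_plumes: dict[int, PlumeSet],
    observed_plumes: dict[int, PlumeSet],
    daily_monitor: pd.DataFrame,
    days: list[int],
    dates: list,
    coverage_threshold: float = 0.5,
    use_all_grids: bool = False,
) -> pd.DataFrame:
    """Assemble the per-area-day exposure table with lag 0-1 columns.

    Days whose forecast grid is unavailable yield missing forecast PM2.5 and
    missing forecast-plume flags (complete-case downstream). Monitor exposure
    is missing only when every monitor is missing that day.

    Parameters
    ----------
    use_all_grids : bool
        If True, ignore grid availability flags (used to compute the true,
        fully observed exposure series of a synthetic scenario).
    """
    pts = region.population_points.sort_values(
        ["area_id", "point_id"], kind="stable")
    area_ids = np.array(sorted(pts["area_id"].unique()), dtype=object)
    codes = pd.Categorical(pts["area_id"], categories=area_ids).codes
    n_areas = len(area_ids)
    x = pts["x_km"].to_numpy()
    y = pts["y_km"].to_numpy()
    w = pts["population"].to_numpy(dtype=float)
    w_tot = np.bincount(codes, weights=w, minlength=n_areas)
    if np.any(np.bincount(codes, minlength=n_areas) == 0):
        raise ValueError("every area must contain at least one population point")

    def pw_mean(values: np.ndarray) -> np.ndarray:
        """Per-area population-weighted mean with pairwise NaN exclusion."""
        ok = ~np.isnan(values)
        num = np.bincount(codes[ok], weights=(values * w)[ok], minlength=n_areas)
        den = np.bincount(codes[ok], weights=w[ok], minlength=n_areas)
        with np.errstate(invalid="ignore"):
            return np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)

    def coverage_flags(plume: PlumeSet | None) -> np.ndarray:
        if plume is None:
            return np.zeros(n_areas)
        if plume.is_empty():
            return np.zeros(n_areas)
        union = plume.union()
        shapely.prepare(union)
        covered = shapely.intersects(union, shapely.points(x, y))
        frac = np.bincount(codes[covered], weights=w[covered],
                           minlength=n_areas) / w_tot
        return (frac > coverage_threshold).astype(float)

    day_to_date = dict(zip(days, dates))
    frames = []
    for day in days:
        date = day_to_date[day]
        grid = grids.get(day)
        grid_ok = grid is not None and (grid.available or use_all_grids)
        if grid_ok:
            f_pm = pw_mean(grid_value_at_points(grid, x, y))
            f_flag = coverage_flags(forecast_plumes.get(day))
        else:
            f_pm = np.full(n_areas, math.nan)
            f_flag = np.full(n_areas, math.nan)
        mvals = nearest_monitor_values(daily_monitor, region.monitors, x, y, date)
        m_pm = pw_mean(mvals)
        o_flag = coverage_flags(observed_plumes.get(day))
        frames.append(pd.DataFrame({
            "area_id": area_ids, "day": day, "date": date,
            "forecast_pm25": f_pm, "monitor_pm25": m_pm,
            "forecast_plume": f_flag, "observed_plume": o_flag,
        }))
    table = pd.concat(frames, ignore_index=True)
    table = table.sort_values(["area_id", "day"], kind="stable").reset_index(drop=True)

    for col, kind in (("forecast_pm25", "continuous"),
                      ("monitor_pm25", "continuous"),
                      ("forecast_plume", "binary"),
                      ("observed_plume", "binary")):
        table[f"lag01_{col}"] = (
            table.groupby("area_id", sort=False)[col]
            .transform(lambda s: lag01(s.to_numpy(), kind=kind))
        )
    n_expected = table["area_id"].nunique() * len(days)
    if len(table) != n_expected:
        raise AssertionError("exposure table is not complete over area-days")
    return table
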