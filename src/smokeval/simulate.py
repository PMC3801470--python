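"""Synthetic study generator with known ground truth.

Emulates the structure of a provincial wildfire-smoke study: health areas
tiling a planar domain, census-unit centroids carrying population weights,
a zero-inflated right-skewed daily forecast field organised into contiguous
smoke episodes advected across days, satellite-analogue observed plumes
(the forecast plume shifted and dilated by a configurable mismatch), hourly
monitor series coupled to the local forecast, and Poisson health counts whose
log-rate responds to the lag 0-1 population-weighted forecast exposure with a
configurable true rate ratio.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import shapely
from shapely import affinity
from shapely.geometry import box

from .config import ScenarioConfig
from .datatypes import GridForecast, PlumeSet, RegionMap, Scenario, TruthRecord
from .exposure import build_exposure_table, derive_forecast_plume, grid_value_at_points

__all__ = [
    "simulate_region_map", "simulate_smoke_fields", "simulate_monitor_obs",
    "simulate_temperature", "simulate_health_counts", "simulate_scenario",
]

_MIN_AREA_SIDE_KM = 1.0


def simulate_region_map(config: ScenarioConfig,
                        rng: np.random.Generator | None = None) -> RegionMap:
    """Tile the square domain into rectangular health areas and place points.

    Areas fill a near-square row/column layout; each area receives a uniform
    number of population points (census-unit centroids) at uniform interior
    positions with uniform populations. Monitors are uniform over the domain.
    """
    rng = rng if rng is not None else config.rng_streams()["region"]
    n = config.n_areas
    L = config.domain_km
    n_rows = max(1, round(math.sqrt(n)))
    base, extra = divmod(n, n_rows)
    cols_per_row = [base + 1 if r < extra else base for r in range(n_rows)]
    if min(cols_per_row) < 1:
        n_rows = n
        cols_per_row = [1] * n
    if L / n_rows < _MIN_AREA_SIDE_KM or L / max(cols_per_row) < _MIN_AREA_SIDE_KM:
        raise ValueError(
            f"domain of {L} km cannot host {n} non-degenerate areas")

    areas: list[tuple[str, shapely.Polygon]] = []
    row_h = L / n_rows
    k = 0
    for r, ncol in enumerate(cols_per_row):
        col_w = L / ncol
        for c in range(ncol):
            k += 1
            areas.append((f"A{k:03d}",
                          box(c * col_w, r * row_h,
                              (c + 1) * col_w, (r + 1) * row_h)))

    lo, hi = config.das_per_area_range
    plo, phi = config.da_pop_range
    rows = []
    for area_id, poly in areas:
        x0, y0, x1, y1 = poly.bounds
        m = int(rng.integers(lo, hi + 1))
        u = rng.uniform(size=m)
        v = rng.uniform(size=m)
        # keep points strictly interior so containment is unambiguous
        xs = x0 + (0.001 + 0.998 * u) * (x1 - x0)
        ys = y0 + (0.001 + 0.998 * v) * (y1 - y0)
        pops = rng.integers(plo, phi + 1, size=m)
        for i in range(m):
            rows.append((f"{area_id}_P{i + 1:04d}", area_id,
                         xs[i], ys[i], int(pops[i])))
    points = pd.DataFrame(
        rows, columns=["point_id", "area_id", "x_km", "y_km", "population"])

    mons = pd.DataFrame({
        "monitor_id": [f"M{i + 1:02d}" for i in range(config.n_monitors)],
        "x_km": rng.uniform(0, L, size=config.n_monitors),
        "y_km": rng.uniform(0, L, size=config.n_monitors),
    })
    return RegionMap(areas=areas, population_points=points, monitors=mons)


def _grow_blob(seed_cell: tuple[int, int], size: int, taken: set,
               shape: tuple[int, int], rng: np.random.Generator) -> list:
    """Randomized edge-connected region growth from a seed cell.

    Returns up to ``size`` cells in accretion order (earliest = core).
    Growth stops early if the frontier is exhausted.
    """
    n_rows, n_cols = shape
    if seed_cell in taken:
        # fall back to a free cell so no episode mass is silently lost
        free = [(i, j) for i in range(n_rows) for j in range(n_cols)
                if (i, j) not in taken]
        if not free:
            return []
        seed_cell = free[int(rng.integers(len(free)))]
    cells = [seed_cell]
    taken.add(seed_cell)
    frontier: list[tuple[int, int]] = []

    def push_neighbours(cell):
        i, j = cell
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = i + di, j + dj
            if 0 <= ni < n_rows and 0 <= nj < n_cols and (ni, nj) not in taken:
                frontier.append((ni, nj))

    push_neighbours(seed_cell)
    while len(cells) < size and frontier:
        idx = int(rng.integers(len(frontier)))
        cell = frontier.pop(idx)
        if cell in taken:
            continue
        taken.add(cell)
        cells.append(cell)
        push_neighbours(cell)
    return cells


def simulate_smoke_fields(
    config: ScenarioConfig,
    region: RegionMap,
    rng: np.random.Generator | None = None,
    mismatch_rng: np.random.Generator | None = None,
    missing_rng: np.random.Generator | None = None,
    derive_plumes: bool = True,
) -> tuple[dict[int, GridForecast], dict[int, PlumeSet]]:
    """Daily forecast grids plus synthetic observed-plume sets.

    Each day the positive-cell count is binomial with success probability
    1 - forecast_zero_prob; positives are grown as contiguous episode blobs
    around advected centres. The innermost fraction of each blob (so that
    core cells make up episode_cell_prob of the domain in expectation)
    receives heavy episode concentrations; the halo receives trace haze.
    Observed plumes are the forecast plume translated by plume_shift_km in a
    per-day random direction and buffered by plume_dilation_km; with both set
    to zero the observed plumes equal the forecast-derived plumes exactly.
    """
    streams = config.rng_streams()
    rng = rng if rng is not None else streams["smoke"]
    mismatch_rng = mismatch_rng if mismatch_rng is not None else streams["plume_mismatch"]
    missing_rng = missing_rng if missing_rng is not None else streams["missing_days"]

    ns = config.n_cells_side
    n_cells = ns * ns
    p_pos = 1.0 - config.forecast_zero_prob
    core_frac = (config.episode_cell_prob / p_pos) if p_pos > 0 else 0.0
    core_frac = min(core_frac, 1.0)
    mu_h, sd_h = config.forecast_lognorm_params
    mu_e, sd_e = config.episode_lognorm_params

    centers = rng.uniform(0, ns, size=(config.n_episodes, 2))
    velocities = rng.uniform(-2.0, 2.0, size=(config.n_episodes, 2))

    missing_days = set(
        missing_rng.choice(np.arange(1, config.n_days + 1),
                           size=config.n_missing_forecast_days, replace=False)
        .tolist()
    ) if config.n_missing_forecast_days else set()

    grids: dict[int, GridForecast] = {}
    observed: dict[int, PlumeSet] = {}
    for day in range(1, config.n_days + 1):
        values = np.zeros((ns, ns))
        n_pos = int(rng.binomial(n_cells, p_pos)) if p_pos > 0 else 0
        if n_pos > 0:
            sizes = rng.multinomial(n_pos, [1.0 / config.n_episodes] * config.n_episodes)
            taken: set = set()
            for e in range(config.n_episodes):
                if sizes[e] == 0:
                    continue
                ci = int(np.clip(round(centers[e, 1]), 0, ns - 1))
                cj = int(np.clip(round(centers[e, 0]), 0, ns - 1))
                cells = _grow_blob((ci, cj), int(sizes[e]), taken, (ns, ns), rng)
                if not cells:
                    continue
                n_core = int(math.ceil(core_frac * len(cells)))
                idx = np.array(cells)
                core, halo = idx[:n_core], idx[n_core:]
                if core.size:
                    values[core[:, 0], core[:, 1]] = rng.lognormal(
                        mu_e, sd_e, size=len(core))
                if halo.size:
                    values[halo[:, 0], halo[:, 1]] = rng.lognormal(
                        mu_h, sd_h, size=len(halo))
        # advect episode centres, reflecting at the domain boundary
        centers = centers + velocities + rng.normal(0, 0.5, size=centers.shape)
        over = centers > ns
        under = centers < 0
        centers[over] = 2 * ns - centers[over]
        centers[under] = -centers[under]
        velocities[over | under] *= -1

        grid = GridForecast(day=day, x0_km=0.0, y0_km=0.0,
                            cell_km=config.grid_cell_km, values=values,
                            available=day not in missing_days)
        grids[day] = grid

        theta = float(mismatch_rng.uniform(0, 2 * math.pi))
        if not derive_plumes:
            continue
        fplume = derive_forecast_plume(grid)
        if fplume.is_empty():
            observed[day] = PlumeSet(day=day, polygons=[], source="observed")
        else:
            geom = fplume.union()
            if config.plume_shift_km > 0:
                geom = affinity.translate(
                    geom,
                    xoff=config.plume_shift_km * math.cos(theta),
                    yoff=config.plume_shift_km * math.sin(theta))
            if config.plume_dilation_km > 0:
                geom = geom.buffer(config.plume_dilation_km)
            polys = list(geom.geoms) if geom.geom_type == "MultiPolygon" else [geom]
            observed[day] = PlumeSet(day=day, polygons=polys, source="observed")
    return grids, observed


def simulate_monitor_obs(
    config: ScenarioConfig,
    region: RegionMap,
    grids: dict[int, GridForecast],
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Hourly monitor series coupled to the co-located forecast.

    The daily mean at each monitor is max(0, coupling * forecast + background
    + daily noise); hourly values scatter multiplicatively around it with the
    within-day jitter centred so the 24-hour mean is exact. A configurable
    fraction of hours carries filter pressure above 60% and random missingness
    (isolated hours plus occasional consecutive runs) for QC testing.
    """
    rng = rng if rng is not None else config.rng_streams()["monitors"]
    mons = region.monitors
    dates = config.dates()
    frames = []
    for day in range(1, config.n_days + 1):
        grid = grids[day]
        f = grid_value_at_points(grid, mons["x_km"].to_numpy(),
                                 mons["y_km"].to_numpy())
        noise = rng.normal(0.0, config.obs_noise_sd, size=len(mons)) \
            if config.obs_noise_sd > 0 else np.zeros(len(mons))
        m = np.maximum(
            0.0, config.agreement_coupling * f + config.obs_background_mean + noise)
        jitter = rng.uniform(-config.hourly_jitter, config.hourly_jitter,
                             size=(len(mons), 24)) if config.hourly_jitter > 0 \
            else np.zeros((len(mons), 24))
        jitter -= jitter.mean(axis=1, keepdims=True)
        hourly = m[:, None] * (1.0 + jitter)

        miss = rng.uniform(size=hourly.shape) < config.hourly_missing_prob
        run_days = rng.uniform(size=len(mons)) < config.consecutive_missing_prob
        for k in np.nonzero(run_days)[0]:
            run_len = int(rng.integers(3, 9))
            start = int(rng.integers(0, 25 - run_len))
            miss[k, start:start + run_len] = True
        hourly = np.where(miss, np.nan, hourly)

        exceed = rng.uniform(size=hourly.shape) < config.pressure_exceed_prob
        pressure = np.where(exceed, rng.uniform(61, 95, size=hourly.shape),
                            rng.uniform(10, 55, size=hourly.shape))

        base_ts = pd.Timestamp(dates[day - 1])
        ts = base_ts + pd.to_timedelta(np.arange(24), unit="h")
        frames.append(pd.DataFrame({
            "monitor_id": np.repeat(mons["monitor_id"].to_numpy(), 24),
            "timestamp": np.tile(ts, len(mons)),
            "pm25": hourly.ravel(),
            "filter_pressure_pct": pressure.ravel(),
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_temperature(config: ScenarioConfig,
                         region: RegionMap,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-monitor daily maximum temperature: smooth seasonal wave + noise."""
    rng = rng if rng is not None else config.rng_streams()["temperature"]
    days = np.arange(1, config.n_days + 1)
    rows = []
    for mid in region.monitors["monitor_id"]:
        phase = rng.uniform(0, 70)
        noise = rng.normal(0, config.temp_noise_sd_c, size=len(days))
        tmax = (config.temp_base_c
                + config.temp_amplitude_c * np.sin(2 * np.pi * (days + phase) / 70.0)
                + noise)
        rows.append(pd.DataFrame({"monitor_id": mid, "day": days, "tmax_c": tmax}))
    return pd.concat(rows, ignore_index=True)


def area_temperature(region: RegionMap, temperature: pd.DataFrame) -> pd.DataFrame:
    """Assign each area the series of the monitor closest to its centroid."""
    cents = region.area_centroids()
    mons = region.monitors.sort_values("monitor_id", kind="stable")
    dx = cents["x_km"].to_numpy()[:, None] - mons["x_km"].to_numpy()[None, :]
    dy = cents["y_km"].to_numpy()[:, None] - mons["y_km"].to_numpy()[None, :]
    nearest = mons["monitor_id"].to_numpy()[np.argmin(dx * dx + dy * dy, axis=1)]
    lookup = pd.DataFrame({"area_id": cents["area_id"], "monitor_id": nearest})
    out = lookup.merge(temperature, on="monitor_id")
    return out[["area_id", "day", "tmax_c"]]


def simulate_health_counts(
    config: ScenarioConfig,
    region: RegionMap,
    exposures: pd.DataFrame,
    temperature: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Poisson area-day counts for each configured outcome, plus ground truth.

    log rate per person-day = per-area weekday log baseline
    + beta_exposure * lag 0-1 population-weighted forecast PM2.5
    + log(weekend multiplier) on weekends/holidays
    + temperature slope * (tmax - reference) [+ lognormal overdispersion].
    Counts are Poisson with mean rate * population.
    """
    rng = rng if rng is not None else config.rng_streams()["health"]
    if (region.population_points["population"] <= 0).any():
        raise ValueError("populations must be positive")
    pops = (region.population_points.groupby("area_id", sort=True)["population"]
            .sum())
    dates = config.dates()
    area_tmax = area_temperature(region, temperature)

    exp_col = "lag01_forecast_pm25"
    if exp_col not in exposures.columns:
        raise ValueError(f"exposure table lacks {exp_col}")
    carry = [c for c in ("area_id", "day", "forecast_pm25", exp_col)
             if c in exposures.columns]
    base = exposures[carry].merge(area_tmax, on=["area_id", "day"], how="left")
    if base[exp_col].isna().any():
        raise ValueError("truth exposure table must be complete (no missing)")

    all_areas = sorted(pops.index)
    panels = []
    true_betas: dict[str, dict[str, float]] = {}
    true_intercepts: dict[str, dict[str, float]] = {}
    for name in sorted(config.outcomes):
        oc = config.outcomes[name]
        areas = all_areas
        if oc.n_areas_with_data is not None and oc.n_areas_with_data < len(all_areas):
            keep = rng.choice(len(all_areas), size=oc.n_areas_with_data,
                              replace=False)
            areas = sorted(np.asarray(all_areas, dtype=object)[np.sort(keep)])
        lo, hi = oc.baseline_rate_range
        log_base = rng.uniform(math.log(lo), math.log(hi), size=len(areas))
        base_rates = dict(zip(areas, log_base))  # log events /100k person-days

        df = base[base["area_id"].isin(areas)].copy()
        df["date"] = [dates[d - 1] for d in df["day"]]
        dow = pd.to_datetime(df["date"]).dt.dayofweek
        df["day_of_week"] = dow.to_numpy()
        df["holiday_flag"] = df["day"].isin(config.holiday_days).astype(int)
        df["study_week"] = (df["day"] - 1) // 7 + 1
        df["population"] = df["area_id"].map(pops).astype(int)
        wknd = ((df["day_of_week"] >= 5) | (df["holiday_flag"] == 1)).to_numpy()

        beta = oc.beta_per_ugm3
        log_rate = (df["area_id"].map(base_rates).to_numpy()
                    - math.log(1e5)
                    + beta * df[exp_col].to_numpy()
                    + np.where(wknd, math.log(oc.weekend_rate_multiplier), 0.0)
                    + config.temperature_effect_per_degc
                    * (df["tmax_c"].to_numpy() - config.temp_base_c))
        if config.overdispersion_sd > 0:
            od = rng.normal(-config.overdispersion_sd ** 2 / 2.0,
                            config.overdispersion_sd, size=len(df))
            log_rate = log_rate + od
        lam = df["population"].to_numpy() * np.exp(log_rate)
        df["count"] = rng.poisson(lam)
        df["outcome"] = name
        df = df.rename(columns={"tmax_c": "tmax"})
        panels.append(df[["area_id", "day", "date", "outcome", "count",
                          "population", "tmax", "day_of_week", "holiday_flag",
                          "study_week"]])
        true_betas[name] = {
            "exposure_per_ugm3": beta,
            "log_weekend_multiplier": math.log(oc.weekend_rate_multiplier),
            "temperature_per_degc": config.temperature_effect_per_degc,
        }
        true_intercepts[name] = {a: float(b - math.log(1e5))
                                 for a, b in base_rates.items()}

    panel = pd.concat(panels, ignore_index=True)
    truth = TruthRecord(true_betas=true_betas,
                        true_area_intercepts=true_intercepts,
                        realized_exposures=base.copy())
    return panel, truth


def simulate_scenario(config: ScenarioConfig,
                      with_plume_flags: bool = True) -> Scenario:
    """Generate a full scenario: geography, fields, observations, outcomes.

    ``with_plume_flags=False`` skips forecast/observed plume derivation for
    speed when only the continuous-exposure pathway is needed (e.g. replicated
    parameter-recovery studies).
    """
    streams = config.rng_streams()
    region = simulate_region_map(config, streams["region"])
    grids, observed = simulate_smoke_fields(
        config, region, rng=streams["smoke"],
        mismatch_rng=streams["plume_mismatch"],
        missing_rng=streams["missing_days"],
        derive_plumes=with_plume_flags)
    fplumes = ({d: derive_forecast_plume(g) for d, g in grids.items()}
               if with_plume_flags else {})
    hourly = simulate_monitor_obs(config, region, grids, rng=streams["monitors"])
    temperature = simulate_temperature(config, region, rng=streams["temperature"])

    days = list(range(1, config.n_days + 1))
    empty_daily = pd.DataFrame(columns=["monitor_id", "date", "value"])
    true_expo = build_exposure_table(
        region, grids, {}, {}, empty_daily, days, config.dates(),
        use_all_grids=True)
    panel, truth = simulate_health_counts(
        config, region, true_expo, temperature, rng=streams["health"])
    return Scenario(config=config, region=region, grids=grids,
                    forecast_plumes=fplumes, observed_plumes=observed,
                    hourly_obs=hourly, temperature=temperature,
                    health_panel=panel, truth=truth)
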