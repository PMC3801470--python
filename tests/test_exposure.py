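"""Exposure assignment: grid lookup, nearest monitor, weighting, plumes, lags."""

import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from smokeval.datatypes import GridForecast, PlumeSet
from smokeval.exposure import (
    build_exposure_table, daily_plume_union, derive_forecast_plume,
    grid_value_at_points, lag01, nearest_monitor_values,
    plume_coverage_flag, population_weighted_mean,
)
from smokeval.qc import apply_pressure_filter, daily_averages


def make_grid(values, cell_km=10.0, x0=0.0, y0=0.0, day=1, available=True):
    return GridForecast(day=day, x0_km=x0, y0_km=y0, cell_km=cell_km,
                        values=np.asarray(values, dtype=float),
                        available=available)


class TestGridLookup:
    def test_cell_centers(self):
        g = make_grid([[1.0, 2.0], [3.0, 4.0]])
        # row index = y, col index = x
        vals = grid_value_at_points(g, [5.0, 15.0, 5.0, 15.0],
                                    [5.0, 5.0, 15.0, 15.0])
        np.testing.assert_allclose(vals, [1.0, 2.0, 3.0, 4.0])

    def test_outside_grid_is_zero(self):
        g = make_grid([[7.0]])
        vals = grid_value_at_points(g, [-1.0, 11.0, 5.0], [5.0, 5.0, -0.1])
        np.testing.assert_allclose(vals, [0.0, 0.0, 0.0])

    def test_half_open_shared_edge(self):
        g = make_grid([[1.0, 2.0]])
        # x=10 is the shared edge: belongs to the increasing-side cell
        assert grid_value_at_points(g, [10.0], [5.0])[0] == 2.0
        # x=20 is the outer max edge: outside
        assert grid_value_at_points(g, [20.0], [5.0])[0] == 0.0

    def test_origin_offset(self):
        g = make_grid([[5.0]], x0=100.0, y0=200.0)
        assert grid_value_at_points(g, [105.0], [205.0])[0] == 5.0
        assert grid_value_at_points(g, [5.0], [5.0])[0] == 0.0


def monitor_frames(positions, values, date="2010-07-05"):
    monitors = pd.DataFrame(
        [{"monitor_id": mid, "x_km": x, "y_km": y}
         for mid, (x, y) in positions.items()])
    daily = pd.DataFrame(
        [{"monitor_id": mid, "date": pd.Timestamp(date).date(), "value": v}
         for mid, v in values.items()])
    return daily, monitors, pd.Timestamp(date).date()


class TestNearestMonitor:
    def test_picks_closest(self):
        daily, monitors, d = monitor_frames(
            {"M1": (0.0, 0.0), "M2": (10.0, 0.0)}, {"M1": 3.0, "M2": 9.0})
        vals = nearest_monitor_values(daily, monitors, [1.0, 9.0], [0.0, 0.0], d)
        np.testing.assert_allclose(vals, [3.0, 9.0])

    def test_skips_missing_monitor(self):
        daily, monitors, d = monitor_frames(
            {"M1": (0.0, 0.0), "M2": (10.0, 0.0)},
            {"M1": np.nan, "M2": 9.0})
        vals = nearest_monitor_values(daily, monitors, [1.0], [0.0], d)
        assert vals[0] == 9.0

    def test_all_missing_gives_nan(self):
        daily, monitors, d = monitor_frames(
            {"M1": (0.0, 0.0)}, {"M1": np.nan})
        assert math.isnan(nearest_monitor_values(daily, monitors,
                                                 [1.0], [0.0], d)[0])

    def test_tie_broken_by_monitor_id(self):
        daily, monitors, d = monitor_frames(
            {"M2": (-5.0, 0.0), "M1": (5.0, 0.0)}, {"M2": 7.0, "M1": 3.0})
        # equidistant from origin: lexicographically smaller id (M1) wins
        assert nearest_monitor_values(daily, monitors, [0.0], [0.0], d)[0] == 3.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(7)
        pos = {f"M{i:02d}": tuple(rng.uniform(0, 100, 2)) for i in range(8)}
        vals = {m: (np.nan if rng.uniform() < 0.3 else float(rng.uniform(0, 30)))
                for m in pos}
        daily, monitors, d = monitor_frames(pos, vals)
        xs, ys = rng.uniform(0, 100, 50), rng.uniform(0, 100, 50)
        got = nearest_monitor_values(daily, monitors, xs, ys, d)
        ok = sorted(m for m in pos if not np.isnan(vals[m]))
        for k in range(50):
            dists = [(math.hypot(xs[k] - pos[m][0], ys[k] - pos[m][1]), m)
                     for m in ok]
            best = min(dists)[1]
            assert got[k] == vals[best]


class TestPopulationWeightedMean:
    def test_hand_example(self):
        assert population_weighted_mean([10.0, 20.0], [100, 300]) == 17.5

    def test_pairwise_nan_exclusion(self):
        assert population_weighted_mean([5.0, np.nan, 15.0],
                                        [100, 600, 300]) == 12.5

    def test_empty_and_all_missing_give_nan(self):
        assert math.isnan(population_weighted_mean([], []))
        assert math.isnan(population_weighted_mean([np.nan], [100]))

    def test_nonpositive_population_rejected(self):
        with pytest.raises(ValueError):
            population_weighted_mean([1.0, 2.0], [100, 0])


def plume(day, *geoms, source="observed"):
    return PlumeSet(day=day, polygons=list(geoms), source=source)


class TestCoverageFlag:
    def test_majority_covered(self):
        p = plume(1, box(0, 0, 10, 10))
        # 60% of population inside
        assert plume_coverage_flag(p, [5.0, 20.0], [5.0, 5.0], [600, 400]) == 1

    def test_exactly_half_not_flagged(self):
        p = plume(1, box(0, 0, 10, 10))
        assert plume_coverage_flag(p, [5.0, 20.0], [5.0, 5.0], [500, 500]) == 0

    def test_empty_plume_is_zero(self):
        assert plume_coverage_flag(plume(1), [5.0], [5.0], [100]) == 0

    def test_boundary_point_counts_inside(self):
        p = plume(1, box(0, 0, 10, 10))
        assert plume_coverage_flag(p, [10.0, 50.0], [5.0, 5.0], [600, 400]) == 1

    def test_monotone_under_dilation(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            xs, ys = rng.uniform(0, 40, 10), rng.uniform(0, 40, 10)
            w = rng.uniform(1, 10, 10)
            base = box(*np.sort(rng.uniform(0, 40, 2)),
                       *np.sort(rng.uniform(0, 40, 2)))
            small = plume(1, base)
            big = plume(1, base.buffer(5.0))
            assert plume_coverage_flag(big, xs, ys, w) >= \
                plume_coverage_flag(small, xs, ys, w)

    def test_no_points_rejected(self):
        with pytest.raises(ValueError):
            plume_coverage_flag(plume(1, box(0, 0, 1, 1)), [], [], [])


class TestDeriveForecastPlume:
    def test_single_positive_cell(self):
        g = make_grid([[0.0, 3.0], [0.0, 0.0]])
        p = derive_forecast_plume(g)
        assert p.area == pytest.approx(100.0)
        assert p.union().bounds == (10.0, 0.0, 20.0, 10.0)

    def test_adjacent_cells_merge(self):
        g = make_grid([[1.0, 2.0]])
        p = derive_forecast_plume(g)
        assert len(p.polygons) == 1
        assert p.area == pytest.approx(200.0)

    def test_area_equals_cell_area_times_count(self):
        rng = np.random.default_rng(13)
        vals = np.where(rng.uniform(size=(12, 12)) < 0.3,
                        rng.uniform(0.1, 50, (12, 12)), 0.0)
        p = derive_forecast_plume(make_grid(vals))
        assert p.area == pytest.approx(100.0 * np.count_nonzero(vals))

    def test_all_zero_grid_is_empty(self):
        p = derive_forecast_plume(make_grid(np.zeros((3, 3))))
        assert p.is_empty()


class TestDailyPlumeUnion:
    def test_disjoint_areas_add(self):
        u = daily_plume_union([plume(2, box(0, 0, 1, 1)),
                               plume(2, box(5, 5, 6, 6))])
        assert u.area == pytest.approx(2.0)
        assert u.day == 2

    def test_overlap_counted_once(self):
        u = daily_plume_union([plume(1, box(0, 0, 1, 1)),
                               plume(1, box(0.5, 0, 1.5, 1))])
        assert u.area == pytest.approx(1.5)

    def test_mixed_days_rejected(self):
        with pytest.raises(ValueError):
            daily_plume_union([plume(1, box(0, 0, 1, 1)),
                               plume(2, box(0, 0, 1, 1))])


class TestLag01:
    def test_continuous_mean(self):
        np.testing.assert_allclose(lag01([10.0, 20.0]), [10.0, 15.0])

    def test_binary_max(self):
        np.testing.assert_allclose(lag01([0.0, 1.0, 0.0], kind="binary"),
                                   [0.0, 1.0, 1.0])

    def test_missing_previous_falls_back_to_same_day(self):
        out = lag01([np.nan, 8.0, 12.0])
        assert math.isnan(out[0])
        assert out[1] == 8.0
        assert out[2] == 10.0

    def test_missing_same_day_stays_missing(self):
        out = lag01([4.0, np.nan, 6.0])
        assert out[0] == 4.0
        assert math.isnan(out[1])
        assert out[2] == 6.0  # previous missing -> same-day fallback


class TestExposureTable:
    def test_complete_over_area_days(self, small_scenario):
        sc = small_scenario
        daily = daily_averages(apply_pressure_filter(sc.hourly_obs))
        days = sorted(sc.grids)
        table = build_exposure_table(
            sc.region, sc.grids, sc.forecast_plumes, sc.observed_plumes,
            daily, days, list(sc.config.dates()))
        n_areas = len(sc.region.areas)
        assert len(table) == n_areas * len(days)
        assert not table.duplicated(["area_id", "day"]).any()
        for col in ("forecast_pm25", "monitor_pm25", "forecast_plume",
                    "observed_plume", "lag01_forecast_pm25"):
            assert col in table.columns

    def test_unavailable_days_missing_forecast_only(self, small_scenario):
        sc = small_scenario
        daily = daily_averages(apply_pressure_filter(sc.hourly_obs))
        days = sorted(sc.grids)
        table = build_exposure_table(
            sc.region, sc.grids, sc.forecast_plumes, sc.observed_plumes,
            daily, days, list(sc.config.dates()))
        missing_days = [d for d in days if not sc.grids[d].available]
        assert missing_days, "small config should include a missing day"
        sub = table[table["day"].isin(missing_days)]
        assert sub["forecast_pm25"].isna().all()
        assert sub["forecast_plume"].isna().all()
        assert sub["monitor_pm25"].notna().any()

    def test_matches_reference_per_area_operations(self, small_scenario):
        sc = small_scenario
        daily = daily_averages(apply_pressure_filter(sc.hourly_obs))
        days = sorted(sc.grids)
        dates = list(sc.config.dates())
        table = build_exposure_table(
            sc.region, sc.grids, sc.forecast_plumes, sc.observed_plumes,
            daily, days, dates)
        pts = sc.region.population_points
        rng = np.random.default_rng(3)
        check_days = rng.choice(days, size=4, replace=False)
        for day in check_days:
            date = dates[days.index(day)]
            grid = sc.grids[day]
            for area_id in list(dict(sc.region.areas))[:5]:
                ap = pts[pts["area_id"] == area_id]
                x, y = ap["x_km"].to_numpy(), ap["y_km"].to_numpy()
                w = ap["population"].to_numpy()
                row = table[(table["area_id"] == area_id)
                            & (table["day"] == day)].iloc[0]
                if grid.available:
                    want = population_weighted_mean(
                        grid_value_at_points(grid, x, y), w)
                    assert row["forecast_pm25"] == pytest.approx(want)
                    fp = sc.forecast_plumes.get(day)
                    if fp is not None:
                        assert row["forecast_plume"] == plume_coverage_flag(
                            fp, x, y, w)
                else:
                    assert math.isnan(row["forecast_pm25"])
                mvals = nearest_monitor_values(daily, sc.region.monitors,
                                               x, y, date)
                want_m = population_weighted_mean(mvals, w)
                if math.isnan(want_m):
                    assert math.isnan(row["monitor_pm25"])
                else:
                    assert row["monitor_pm25"] == pytest.approx(want_m)
                op = sc.observed_plumes.get(day)
                if op is not None:
                    assert row["observed_plume"] == plume_coverage_flag(
                        op, x, y, w)

    def test_lag_columns_match_lag01(self, small_scenario):
        sc = small_scenario
        daily = daily_averages(apply_pressure_filter(sc.hourly_obs))
        days = sorted(sc.grids)
        table = build_exposure_table(
            sc.region, sc.grids, sc.forecast_plumes, sc.observed_plumes,
            daily, days, list(sc.config.dates()))
        one = table[table["area_id"] == table["area_id"].iloc[0]]
        np.testing.assert_allclose(
            one["lag01_forecast_pm25"].to_numpy(),
            lag01(one["forecast_pm25"].to_numpy()))
        np.testing.assert_allclose(
            one["lag01_observed_plume"].to_numpy(),
            lag01(one["observed_plume"].to_numpy(), kind="binary"))
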