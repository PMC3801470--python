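"""Synthetic scenario generator: geography, fields, observations, truth."""

import math

import numpy as np
import pandas as pd
import pytest
from shapely.ops import unary_union

from conftest import small_config, small_outcomes
from smokeval.config import OutcomeConfig, ScenarioConfig
from smokeval.exposure import grid_value_at_points
from smokeval.qc import apply_pressure_filter, daily_averages
from smokeval.simulate import (
    simulate_monitor_obs, simulate_region_map, simulate_scenario,
    simulate_smoke_fields,
)
from smokeval.studies import global_agreement
from smokeval.verification import fms


class TestRegionMap:
    def test_areas_tile_the_domain(self):
        cfg = small_config()
        region = simulate_region_map(cfg)
        assert len(region.areas) == cfg.n_areas
        union = unary_union([poly for _, poly in region.areas])
        assert union.area == pytest.approx(cfg.domain_km ** 2)

    def test_points_inside_their_area(self):
        region = simulate_region_map(small_config())
        polys = dict(region.areas)
        for aid, grp in region.population_points.groupby("area_id"):
            poly = polys[aid]
            for _, row in grp.iterrows():
                assert poly.contains(
                    __import__("shapely").geometry.Point(row["x_km"], row["y_km"]))

    def test_point_counts_and_populations_in_range(self):
        cfg = ScenarioConfig(seed=2)
        region = simulate_region_map(cfg)
        counts = region.population_points.groupby("area_id").size()
        lo, hi = cfg.das_per_area_range
        assert counts.between(lo, hi).all()
        plo, phi = cfg.da_pop_range
        assert region.population_points["population"].between(plo, phi).all()
        assert len(region.monitors) == cfg.n_monitors

    def test_deterministic_under_seed(self):
        a = simulate_region_map(small_config())
        b = simulate_region_map(small_config())
        pd.testing.assert_frame_equal(a.population_points, b.population_points)
        pd.testing.assert_frame_equal(a.monitors, b.monitors)

    def test_degenerate_domain_rejected(self):
        with pytest.raises(ValueError):
            simulate_region_map(small_config(domain_km=3.0, n_areas=12))


class TestSmokeFields:
    def test_pooled_marginals_match_targets(self, default_scenario):
        vals = np.concatenate(
            [g.values.ravel() for g in default_scenario.grids.values()])
        zero_frac = float(np.mean(vals == 0.0))
        assert zero_frac >= 0.5
        assert vals.mean() == pytest.approx(4.0, rel=0.25)
        assert vals.std() == pytest.approx(27.3, rel=0.25)
        assert np.all(vals >= 0.0)

    def test_missing_day_count(self, default_scenario):
        cfg = default_scenario.config
        missing = [d for d, g in default_scenario.grids.items()
                   if not g.available]
        assert len(missing) == cfg.n_missing_forecast_days

    def test_zero_probability_one_gives_empty_fields(self):
        cfg = small_config(forecast_zero_prob=1.0)
        region = simulate_region_map(cfg)
        grids, observed = simulate_smoke_fields(cfg, region)
        assert all(np.all(g.values == 0.0) for g in grids.values())
        assert all(p.is_empty() for p in observed.values())

    def test_zero_mismatch_reproduces_forecast_plume_exactly(self):
        cfg = small_config(plume_shift_km=0.0, plume_dilation_km=0.0)
        sc = simulate_scenario(cfg)
        checked = 0
        for day, fp in sc.forecast_plumes.items():
            op = sc.observed_plumes[day]
            if fp.is_empty() and op.is_empty():
                continue
            assert fms(fp, op) == pytest.approx(1.0)
            checked += 1
        assert checked > 0

    def test_observed_plume_area_grows_with_dilation(self):
        base = small_config(plume_shift_km=0.0, plume_dilation_km=0.0)
        dil = small_config(plume_shift_km=0.0, plume_dilation_km=20.0)
        a = simulate_scenario(base).observed_plumes
        b = simulate_scenario(dil).observed_plumes
        for day in a:
            if not a[day].is_empty():
                assert b[day].area > a[day].area


class TestMonitorObs:
    def clean_config(self, **extra):
        kw = dict(
            agreement_coupling=1.0, obs_noise_sd=0.0, obs_background_mean=0.0,
            pressure_exceed_prob=0.0, hourly_missing_prob=0.0,
            consecutive_missing_prob=0.0, n_missing_forecast_days=0)
        kw.update(extra)
        return small_config(**kw)

    def test_clean_daily_mean_equals_colocated_forecast(self):
        cfg = self.clean_config()
        region = simulate_region_map(cfg)
        grids, _ = simulate_smoke_fields(cfg, region, derive_plumes=False)
        hourly = simulate_monitor_obs(cfg, region, grids)
        daily = daily_averages(apply_pressure_filter(hourly))
        dates = list(cfg.dates())
        for day in range(1, cfg.n_days + 1):
            f = grid_value_at_points(grids[day], region.monitors["x_km"],
                                     region.monitors["y_km"])
            sub = daily[daily["date"] == dates[day - 1]].set_index("monitor_id")
            got = sub.loc[region.monitors["monitor_id"], "value"].to_numpy()
            np.testing.assert_allclose(got, f, atol=1e-9)

    def test_forced_consecutive_missingness_blanks_every_day(self):
        cfg = self.clean_config(consecutive_missing_prob=1.0)
        region = simulate_region_map(cfg)
        grids, _ = simulate_smoke_fields(cfg, region, derive_plumes=False)
        hourly = simulate_monitor_obs(cfg, region, grids)
        daily = daily_averages(apply_pressure_filter(hourly))
        assert daily["value"].isna().all()
        assert (daily["missing_reason"] != "none").all()

    def test_pressure_channel_within_bounds(self, small_scenario):
        p = small_scenario.hourly_obs["filter_pressure_pct"]
        assert p.between(10, 95).all()

    def test_zero_coupling_decorrelates_forecast_and_obs(self):
        res = global_agreement(ScenarioConfig(agreement_coupling=0.0, seed=3))
        assert res["n_pairs"] > 500
        assert abs(res["global_r"]) < 0.1


class TestHealthCounts:
    def test_panel_complete_over_area_days(self, small_scenario):
        cfg = small_scenario.config
        panel = small_scenario.health_panel
        for name in cfg.outcomes:
            sub = panel[panel["outcome"] == name]
            assert len(sub) == cfg.n_areas * cfg.n_days
            assert not sub.duplicated(["area_id", "day"]).any()
        assert (panel["count"] >= 0).all()
        assert (panel["population"] > 0).all()

    def test_truth_beta_encodes_configured_rate_ratio(self, small_scenario):
        cfg = small_scenario.config
        for name, oc in cfg.outcomes.items():
            beta = small_scenario.truth.true_betas[name]["exposure_per_ugm3"]
            assert math.exp(30.0 * beta) == pytest.approx(oc.true_rr_per_30)

    def test_weekend_rate_multiplier_recovered_under_null_exposure(self):
        oc = OutcomeConfig(true_rr_per_30=1.0, baseline_rate_range=(29.9, 30.1),
                           weekend_rate_multiplier=0.42,
                           n_areas_with_data=None)
        cfg = small_config(n_areas=30, n_days=28, das_per_area_range=(3, 60),
                           outcomes={"dispensations": oc},
                           overdispersion_sd=0.0,
                           temperature_effect_per_degc=0.0, seed=21)
        panel = simulate_scenario(cfg, with_plume_flags=False).health_panel
        wknd = (panel["day_of_week"] >= 5) | (panel["holiday_flag"] == 1)
        py_w = panel.loc[wknd, "population"].sum()
        py_d = panel.loc[~wknd, "population"].sum()
        ratio = (panel.loc[wknd, "count"].sum() / py_w) \
            / (panel.loc[~wknd, "count"].sum() / py_d)
        assert ratio == pytest.approx(0.42, rel=0.08)

    def test_outcome_area_subset_respected(self):
        outcomes = dict(small_outcomes())
        outcomes["visits"] = OutcomeConfig(
            true_rr_per_30=1.05, baseline_rate_range=(2.7, 21.1),
            weekend_rate_multiplier=0.32, n_areas_with_data=8)
        cfg = small_config(outcomes=outcomes)
        panel = simulate_scenario(cfg, with_plume_flags=False).health_panel
        assert panel[panel["outcome"] == "visits"]["area_id"].nunique() == 8
        assert panel[panel["outcome"] == "dispensations"]["area_id"].nunique() \
            == cfg.n_areas


class TestScenarioDeterminism:
    def test_same_seed_reproduces_scenario(self):
        a = simulate_scenario(small_config())
        b = simulate_scenario(small_config())
        pd.testing.assert_frame_equal(a.health_panel, b.health_panel)
        pd.testing.assert_frame_equal(a.hourly_obs, b.hourly_obs)
        for day in a.grids:
            np.testing.assert_array_equal(a.grids[day].values,
                                          b.grids[day].values)

    def test_plume_skip_does_not_change_other_outputs(self):
        a = simulate_scenario(small_config(), with_plume_flags=True)
        b = simulate_scenario(small_config(), with_plume_flags=False)
        pd.testing.assert_frame_equal(a.health_panel, b.health_panel)
        pd.testing.assert_frame_equal(a.hourly_obs, b.hourly_obs)

    def test_different_seeds_differ(self):
        a = simulate_scenario(small_config(seed=11))
        b = simulate_scenario(small_config(seed=12))
        assert not a.health_panel["count"].equals(b.health_panel["count"])
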