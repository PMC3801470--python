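import pytest

from smokeval.config import OutcomeConfig, ScenarioConfig
from smokeval.exposure import build_exposure_table
from smokeval.qc import apply_pressure_filter, daily_averages
from smokeval.simulate import simulate_scenario


def exposure_table_for(scenario, daily_monitor=None):
    if daily_monitor is None:
        daily_monitor = daily_averages(
            apply_pressure_filter(scenario.hourly_obs))
    days = sorted(scenario.grids)
    return build_exposure_table(
        scenario.region, scenario.grids, scenario.forecast_plumes,
        scenario.observed_plumes, daily_monitor, days,
        list(scenario.config.dates()))


def small_outcomes():
    return {
        "dispensations": OutcomeConfig(
            true_rr_per_30=1.08, baseline_rate_range=(17.7, 72.2),
            weekend_rate_multiplier=0.42, n_areas_with_data=None),
    }


def small_config(**overrides) -> ScenarioConfig:
    """A 12-area, 10-day scenario for fast unit tests."""
    defaults = dict(
        n_areas=12, n_days=10, n_monitors=6,
        das_per_area_range=(3, 20), da_pop_range=(400, 700),
        domain_km=200.0, n_missing_forecast_days=1,
        outcomes=small_outcomes(), seed=11,
    )
    defaults.update(overrides)
    return ScenarioConfig(**defaults)


@pytest.fixture(scope="session")
def small_scenario():
    return simulate_scenario(small_config())


@pytest.fixture(scope="session")
def default_scenario():
    """Full study-scale scenario (89 areas x 35 days) with plumes."""
    return simulate_scenario(ScenarioConfig(seed=5))


@pytest.fixture(scope="session")
def default_daily_monitor(default_scenario):
    return daily_averages(apply_pressure_filter(default_scenario.hourly_obs))


@pytest.fixture(scope="session")
def small_exposures(small_scenario):
    return exposure_table_for(small_scenario)


@pytest.fixture(scope="session")
def default_exposures(default_scenario, default_daily_monitor):
    return exposure_table_for(default_scenario, default_daily_monitor)
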