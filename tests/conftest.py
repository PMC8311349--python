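import numpy as np
import pandas as pd
import pytest

from heterothermy.io import TemperatureSeries
from heterothermy.synth import (
    EnvironmentConfig,
    IndividualConfig,
    records_to_frame,
    simulate_environment,
    simulate_individual,
)


@pytest.fixture(scope="session")
def season_env():
    """Default outdoor-season ambient series (April–October, 15-min)."""
    return simulate_environment(EnvironmentConfig(seed=1))


@pytest.fixture(scope="session")
def season_sim(season_env):
    """One restricted-food individual over the full outdoor season."""
    icfg = IndividualConfig(individual_id="sim-w1", seed=3, food="restricted")
    records = simulate_individual(icfg, season_env)
    return records, icfg


@pytest.fixture(scope="session")
def season_frame(season_sim):
    records, _ = season_sim
    return records_to_frame(records)


def make_winter_records(
    seed: int,
    t_bmin_true: float = 3.6,
    t_b_noise_sd: float = 0.3,
    days: int = 40,
    m_b: float = 40.0,
    t_a_mean: float = 2.0,
):
    """A cold mid-winter chamber/enclosure month for edge-point analyses.

    Ambient means ~2 °C (configurable) with a 4 °C diel swing and weather
    noise, so the animal spends many torpid hours below its defended
    floor's critical ambient region.
    """
    env_cfg = EnvironmentConfig(
        start_date="2019-06-01",
        end_date=str(pd.Timestamp("2019-06-01") + pd.Timedelta(days=days - 1))[:10],
        t_a_annual_mean=t_a_mean,
        t_a_seasonal_amplitude=0.0,
        t_a_diel_amplitude=4.0,
        t_a_noise_sd=1.0,
        seed=1000 + seed,
    )
    env = simulate_environment(env_cfg)
    icfg = IndividualConfig(
        individual_id=f"winter-{seed}",
        seed=seed,
        food="restricted",
        m_b0=m_b,
        t_bmin_true=t_bmin_true,
        t_b_noise_sd=t_b_noise_sd,
    )
    return simulate_individual(icfg, env), icfg


@pytest.fixture(scope="session")
def winter_sim():
    return make_winter_records(seed=7)


def hourly_series(values, start="2019-06-01", kind="body", cadence_min=60):
    idx = pd.date_range(start, periods=len(values), freq="h")
    return TemperatureSeries("fix", kind, pd.Series(np.asarray(values, float), index=idx), cadence_min)
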