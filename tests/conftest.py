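import numpy as np
import pandas as pd
import pytest

from nichegrowth.simulate import (
    SimulationConfig,
    generate_daily_climate,
    generate_sites,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast, fully stochastic scenario used across module tests."""
    return SimulationConfig(
        n_sites_per_scheme=3,
        n_species_local=2,
        n_species_global=2,
        n_sites_per_species=6,
        years=(2000, 2012),
        rng_seed=42,
    )


@pytest.fixture(scope="session")
def small_network(small_config):
    sites = generate_sites(small_config)
    climate = generate_daily_climate(sites, small_config)
    return sites, climate


@pytest.fixture(scope="session")
def noise_free_config() -> SimulationConfig:
    """Deterministic climate: no monthly anomalies, no daily noise."""
    return SimulationConfig(
        n_sites_per_scheme=2,
        n_species_local=1,
        n_species_global=0,
        n_sites_per_species=4,
        years=(2000, 2006),
        monthly_anom_sd=0.0,
        daily_noise_sd=0.0,
        precip_month_sd=0.0,
        precip_gamma_shape=0.0,
        site_temp_sd=0.0,
        site_precip_sd=0.0,
        process_noise_sd=0.0,
        missing_week_prob=0.0,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def noise_free_network(noise_free_config):
    sites = generate_sites(noise_free_config)
    climate = generate_daily_climate(sites, noise_free_config)
    return sites, climate


def constant_climate(site_ids, years, tmean=10.0, prec_per_day=1.0) -> pd.DataFrame:
    """Flat daily climate helper for arithmetic checks."""
    frames = []
    for s in site_ids:
        dates = pd.date_range(f"{years[0]}-01-01", f"{years[1]}-12-31", freq="D")
        dates = dates[~((dates.month == 2) & (dates.day == 29))]
        frames.append(
            pd.DataFrame(
                {"site_id": s, "date": dates, "tmean_c": tmean, "prec_mm": prec_per_day}
            )
        )
    return pd.concat(frames, ignore_index=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
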