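import numpy as np
import pandas as pd
import pytest

from treegrowth.synthetic import CityConfig, SpeciesSpec, generate_city


def clean_city_config(seed: int = 0, **overrides) -> CityConfig:
    """A city with every stochastic corruption switched off.

    No mortality, no duplicate plantings, no entry errors, no measurement
    noise: linkage should then be perfect and reported DBH is exactly the
    rounded true DBH.
    """
    defaults = dict(
        seed=seed,
        n_streets=40,
        addresses_per_street=50,
        annual_mortality=0.0,
        duplicate_series_prob=0.0,
        circumference_error_prob=0.0,
        digit_error_prob=0.0,
        surveyor_sd={"Volunteer": 0.0, "TreesCount Staff": 0.0, "NYC Parks Staff": 0.0},
        early_measurement_sd=0.0,
        svi_effect=0.0,
    )
    defaults.update(overrides)
    return CityConfig(**defaults)


@pytest.fixture(scope="session")
def small_city():
    """Default-condition city at desk scale (shared, read-only)."""
    return generate_city(CityConfig(seed=7, n_streets=50, addresses_per_street=60))


@pytest.fixture(scope="session")
def clean_city():
    return generate_city(clean_city_config(seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_records(rows, year=2005):
    """Build a normalized census frame from (record_id, zip, address, species, dbh)."""
    df = pd.DataFrame(
        rows, columns=["record_id", "zip", "address_norm", "species_norm", "dbh_in"]
    )
    df["census_year"] = year
    df["address_raw"] = df["address_norm"]
    df["species_raw"] = df["species_norm"]
    df["species_unmapped"] = False
    return df
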