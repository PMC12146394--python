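import datetime as dt

import pytest

import peppersim as ps

PLANTING = dt.date(2022, 5, 3)


@pytest.fixture(scope="session")
def phr18_control():
    return ps.get_parameter_set("PHR18", "control", "greenhouse")


@pytest.fixture(scope="session")
def all_greenhouse_sets():
    return [
        ps.get_parameter_set(a, c, "greenhouse")
        for a in ("PHR18", "PHR23")
        for c in ("control", "heat")
    ]


@pytest.fixture(scope="session")
def optimal_wx():
    """Constant-optimal greenhouse weather: daily mean equals TB (30 C)."""
    return ps.greenhouse_series(35, 25, PLANTING, 160, jitter_sd=0.0, srad_mean=18.0, seed=0)


@pytest.fixture(scope="session")
def field_wx():
    return ps.synth_field_weather("central", [2022], seed=42)


@pytest.fixture
def unlimited_management():
    """Water and N never limiting; no auto-irrigation."""
    return ps.ManagementSpec(
        planting_date=PLANTING,
        soil_capacity=1e6,
        initial_soil_water=1e6,
        n_supply=1e5,
        n_release_days=1,
        irrigation_trigger=0.0,
    )


@pytest.fixture
def field_management():
    return ps.ManagementSpec(planting_date=dt.date(2022, 4, 25))
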