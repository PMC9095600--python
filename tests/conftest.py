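from datetime import date

import pytest

from wheatdas.crop_model import (
    IrrigationPolicy,
    PreparedWeather,
    default_crop_params,
    default_soil_params,
)
from wheatdas.synthetic import generate_weather


@pytest.fixture(scope="session")
def crop():
    return default_crop_params()


@pytest.fixture(scope="session")
def soil():
    return default_soil_params()


@pytest.fixture(scope="session")
def policy():
    return IrrigationPolicy(smc=0.21, v=4.0, enabled=True)


@pytest.fixture(scope="session")
def emergence():
    return date(2007, 10, 10)


@pytest.fixture(scope="session")
def weather():
    """One season of seeded synthetic weather starting 2007-09-01."""
    return PreparedWeather(generate_weather(42, date(2007, 9, 1), 400))


def constant_weather(tmean: float, n_days: int = 400, radiation: float = 15.0,
                     start: date = date(2007, 10, 10)) -> PreparedWeather:
    """Weather with constant temperature and radiation (no noise, no rain)."""
    df = generate_weather(0, start, n_days, temp_noise_sd=0.0, wet_prob=0.0)
    df["tmin"] = tmean - 4.0
    df["tmax"] = tmean + 4.0
    df["radiation"] = radiation
    df["precip"] = 2.0  # keep the soil bucket out of stress
    return PreparedWeather(df)
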