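import datetime as dt

import pytest

import lentilsim as ls
from lentilsim.synthetic import ZERO_NOISE, generate_trial


@pytest.fixture(scope="session")
def medium_weather():
    return ls.generate_weather(ls.CLIMATE_CLASSES["medium"], 1, seed=7)


@pytest.fixture(scope="session")
def soil():
    return ls.generate_soil(150.0, 7, seed=1)


@pytest.fixture(scope="session")
def jumbo():
    return ls.get_cultivar("PBA Jumbo2")


@pytest.fixture(scope="session")
def mgmt():
    return ls.ManagementConfig(sowing_date=dt.date(2000, 5, 12))


@pytest.fixture(scope="session")
def zero_noise_trial(jumbo, medium_weather, soil, mgmt):
    """A noiseless parameterization trial plus its generating simulation."""
    return generate_trial(jumbo, medium_weather, soil, mgmt,
                          noise_sd=ZERO_NOISE, seed=0)
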