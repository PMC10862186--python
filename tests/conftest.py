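from datetime import date

import pytest

from ectotemp import heatbudget, weather


@pytest.fixture(scope="session")
def default_params():
    return heatbudget.OrganismParams()


@pytest.fixture(scope="session")
def default_geom(default_params):
    return heatbudget.body_geometry(default_params)


@pytest.fixture(scope="session")
def one_season():
    """One May–July season of synthetic forcing (fixed seed)."""
    cfg = weather.WeatherConfig(start_date=date(2019, 5, 1),
                                end_date=date(2019, 7, 31), seed=7)
    return weather.generate_weather(cfg)
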