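import pytest

from silisim.envgen import EnvSpec, generate_environment
from silisim.sim import SimulationConfig
from silisim.soil import SoilState

SEASON_S = 10279800.0  # default season, a whole number of 1800 s steps


@pytest.fixture(scope="session")
def reference_env():
    """Figure-style environment: PAR 400 for 12 h/day, CO2 400, air 30 degC."""
    return generate_environment(EnvSpec(days=119, tair_day=30.0))


@pytest.fixture(scope="session")
def cool_env():
    """Same recipe at 20 degC air temperature."""
    return generate_environment(EnvSpec(days=119, tair_day=20.0))


@pytest.fixture(scope="session")
def short_env():
    """A 4-day environment for cheap integration tests."""
    return generate_environment(EnvSpec(days=4, tair_day=30.0))


@pytest.fixture
def reference_soil():
    """Figure-1 soil: pH 7, OM 6%, irrigation water at 5 mg/L Si(OH)4."""
    return SoilState(ph=7.0, om=6.0, temperature=25.0, si_water=5.0)


@pytest.fixture
def soil_config(reference_soil):
    return SimulationConfig(mode="soil", si_water=5.0, soil=reference_soil)


@pytest.fixture
def soilless_config():
    return SimulationConfig(mode="soilless", si_water=5.0)


def short_config(mode="soilless", si_water=5.0, soil=None, dt=1800.0, **kw):
    """Config covering the 4-day short_env."""
    return SimulationConfig(
        mode=mode,
        si_water=si_water,
        soil=soil,
        season_length=4 * 86400.0,
        dt=dt,
        **kw,
    )
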