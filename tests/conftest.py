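import numpy as np
import pytest
from hypothesis import settings

from ricetpe.pipeline import best_seasons_and_slices
from ricetpe.synthetic import (
    EnvironmentParams,
    SeasonalCurve,
    SimulationDesign,
    default_varieties,
    make_archetype_grid,
    simulate_grid,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def varieties():
    return default_varieties()


@pytest.fixture()
def small_design():
    return SimulationDesign(sowing_dates_per_year=6, n_years=4)


@pytest.fixture()
def wet_environment():
    """Unlimited water everywhere: rainfed output equals irrigated output."""
    return EnvironmentParams(
        env_id="wet",
        lon=100.0,
        lat=15.0,
        seasonal_yield_curve=SeasonalCurve(amplitude=0.2, phase_doy=200.0),
        monsoon_peak_doy=200.0,
        rain_amplitude=100.0,
        rain_interannual_cv=0.05,
        soil_whc=500.0,
    )


@pytest.fixture(scope="session")
def archetype_grid():
    """One environment per designed TPE regime plus its simulated cubes."""
    envs = make_archetype_grid(18, seed=7)
    cubes = simulate_grid(envs, default_varieties(), seed=7)
    return envs, cubes


@pytest.fixture(scope="session")
def classified_grid(archetype_grid):
    envs, cubes = archetype_grid
    best, slices = best_seasons_and_slices(cubes)
    return envs, cubes, best, slices


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
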