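"""Generator contracts: run enumeration, stress arithmetic, invariants."""

import numpy as np
import pytest

from ricetpe.synthetic import (
    EnvironmentParams,
    SeasonalCurve,
    SimulationDesign,
    VarietyParams,
    enumerate_runs,
    potential_yield,
    simulate_cell,
    stress_indices,
    stress_response,
)
from dataclasses import replace


@pytest.mark.parametrize(
    "kwargs, expected",
    [
        ({}, 672),  # default factorial: 24 dates x 14 years x 2 regimes
        ({"sowing_dates_per_year": 1, "n_years": 1}, 2),
        ({"sowing_dates_per_year": 12}, 336),
    ],
)
def test_enumerate_runs(kwargs, expected):
    assert enumerate_runs(SimulationDesign(**kwargs)) == expected


def test_design_validation():
    with pytest.raises(ValueError):
        SimulationDesign(sowing_dates_per_year=0)
    with pytest.raises(ValueError):
        SimulationDesign(water_regimes=("rainfed",))


def _variety(**kw):
    base = dict(name="v", duration_days=120, potential_yield_max=8.0, veg_sensitivity=1.0, rep_sensitivity=1.0)
    base.update(kw)
    return VarietyParams(**base)


def _environment(**kw):
    base = dict(env_id="e", lon=0.0, lat=0.0)
    base.update(kw)
    return EnvironmentParams(**base)


class TestPotentialYield:
    def test_flat_curve_is_constant_at_maximum(self):
        env = _environment(seasonal_yield_curve=SeasonalCurve(amplitude=0.0))
        var = _variety(potential_yield_max=7.5)
        values = {potential_yield(env, var, doy) for doy in (1, 100, 200, 300)}
        assert values == {7.5}

    def test_sowing_inside_unsuitable_window_is_zero(self):
        env = _environment(unsuitable_window=(100, 150))
        assert potential_yield(env, _variety(), 120) == 0.0
        assert potential_yield(env, _variety(), 160) > 0.0

    def test_wrapping_window(self):
        env = _environment(unsuitable_window=(300, 50))
        assert potential_yield(env, _variety(), 330) == 0.0
        assert potential_yield(env, _variety(), 20) == 0.0
        assert potential_yield(env, _variety(), 150) > 0.0

    def test_deterministic_given_seed(self):
        env = _environment(yield_interannual_cv=0.1)
        a = potential_yield(env, _variety(), 100, 3, master_seed=42)
        b = potential_yield(env, _variety(), 100, 3, master_seed=42)
        assert a == b


class TestStressIndices:
    def test_saturation_when_supply_exceeds_demand(self):
        env = _environment(rain_amplitude=200.0, soil_whc=500.0, rain_interannual_cv=0.0)
        div, dir_ = stress_indices(env, _variety(), 150)
        assert div == 1.0 and dir_ == 1.0

    def test_total_deficit(self):
        env = _environment(rain_amplitude=0.0, soil_whc=0.0)
        div, dir_ = stress_indices(env, _variety(), 150)
        assert div == 0.0 and dir_ == 0.0

    def test_supply_half_demand_gives_half_index(self):
        # no rain; soil buffer delivers exactly half the daily demand
        env = _environment(
            rain_amplitude=0.0, soil_whc=0.5 * 6.0 * 120, demand_mm_day=6.0, rain_interannual_cv=0.0
        )
        div, dir_ = stress_indices(env, _variety(duration_days=120), 150)
        assert div == pytest.approx(0.5)
        assert dir_ == pytest.approx(0.5)


class TestStressResponse:
    def test_no_stress_returns_potential(self):
        assert stress_response(8.0, 1.0, 1.0, _variety()) == 8.0

    def test_total_reproductive_failure(self):
        assert stress_response(8.0, 1.0, 0.0, _variety(rep_sensitivity=2.0)) == 0.0

    def test_power_law_arithmetic(self):
        var = _variety(veg_sensitivity=1.0, rep_sensitivity=2.0)
        assert stress_response(8.0, 0.8, 0.9, var) == pytest.approx(8 * 0.8 * 0.81)

    @pytest.mark.parametrize("bad", [dict(p=-1.0), dict(div=1.5), dict(dir=np.nan)])
    def test_rejects_invalid_inputs(self, bad):
        args = dict(p=8.0, div=0.5, dir=0.5)
        args.update(bad)
        with pytest.raises(ValueError):
            stress_response(args["p"], args["div"], args["dir"], _variety())


class TestSimulateCell:
    def test_unlimited_water_gives_rainfed_equal_irrigated(self, wet_environment, varieties, small_design):
        cube = simulate_cell(wet_environment, varieties, small_design, seed=1)
        np.testing.assert_allclose(cube.a, cube.p)
        assert np.all(cube.div == 1.0) and np.all(cube.dir == 1.0)

    def test_same_seed_is_bit_identical(self, varieties, small_design):
        env = _environment(rain_amplitude=5.0, rain_interannual_cv=0.2, yield_interannual_cv=0.05)
        c1 = simulate_cell(env, varieties, small_design, seed=9)
        c2 = simulate_cell(env, varieties, small_design, seed=9)
        for name in ("p", "a", "div", "dir"):
            assert np.array_equal(getattr(c1, name), getattr(c2, name))

    def test_invariants_hold(self, varieties, small_design):
        env = _environment(rain_amplitude=4.0, rain_interannual_cv=0.3, unsuitable_window=(1, 60))
        cube = simulate_cell(env, varieties, small_design, seed=3)
        cube.validate()  # raises on violation
        assert np.all(cube.a <= cube.p + 1e-12)

    def test_more_rain_never_increases_stress(self, varieties, small_design):
        env = _environment(rain_amplitude=4.0, rain_interannual_cv=0.2, soil_whc=30.0)
        wetter = replace(env, rain_amplitude=env.rain_amplitude * 1.7)
        dry = simulate_cell(env, varieties, small_design, seed=5)
        wet = simulate_cell(wetter, varieties, small_design, seed=5)
        assert np.all(wet.div >= dry.div)
        assert np.all(wet.dir >= dry.dir)
        assert np.all(wet.a >= dry.a - 1e-12)

    def test_variety_list_does_not_perturb_weather(self, varieties, small_design):
        env = _environment(rain_amplitude=4.0, rain_interannual_cv=0.3)
        full = simulate_cell(env, varieties, small_design, seed=2)
        sub = simulate_cell(env, varieties[:3], small_design, seed=2)
        np.testing.assert_array_equal(full.div[:3], sub.div)
        np.testing.assert_array_equal(full.a[:3], sub.a)

    def test_requires_a_variety(self, small_design):
        with pytest.raises(ValueError):
            simulate_cell(_environment(), [], small_design, seed=0)
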