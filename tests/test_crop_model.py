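"""Unit and property tests of the daily crop growth core."""

import math
from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wheatdas.crop_model import (
    CropParams,
    IrrigationPolicy,
    ParameterError,
    SoilParams,
    WeatherError,
    daily_growth,
    default_crop_params,
    default_soil_params,
    run_season,
    senesce_leaves,
    soil_water_step,
    thermal_increment,
    update_phenology,
)
from .conftest import constant_weather


class TestThermalIncrement:
    @pytest.mark.parametrize(
        "tmin,tmax,tbase,expected",
        [(5, 15, 0, 10.0), (-10, -2, 0, 0.0), (0, 0, 0, 0.0), (2, 10, 4, 2.0)],
    )
    def test_values(self, tmin, tmax, tbase, expected):
        assert thermal_increment(tmin, tmax, tbase) == pytest.approx(expected)

    def test_rejects_non_finite_and_inverted(self):
        with pytest.raises(WeatherError):
            thermal_increment(float("nan"), 10, 0)
        with pytest.raises(WeatherError):
            thermal_increment(12, 10, 0)


class TestPhenology:
    def test_anthesis_and_maturity_boundaries(self):
        assert update_phenology(0, 1000, 1000, 800)[1] == pytest.approx(1.0)
        assert update_phenology(1800, 0, 1000, 800)[1] == pytest.approx(2.0)
        assert update_phenology(0, 500, 1000, 800)[1] == pytest.approx(0.5)

    def test_dvs_capped_at_two(self):
        assert update_phenology(5000, 100, 1000, 800)[1] == 2.0

    def test_invalid_thermal_sums(self):
        with pytest.raises(ParameterError):
            update_phenology(0, 10, 0, 800)

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(
        tsum=st.floats(0, 3000),
        inc=st.floats(0, 30),
        t1=st.floats(100, 2000),
        t2=st.floats(100, 2000),
    )
    def test_dvs_monotone_in_thermal_time(self, tsum, inc, t1, t2):
        _, d0 = update_phenology(tsum, 0.0, t1, t2)
        _, d1 = update_phenology(tsum, inc, t1, t2)
        assert d1 >= d0


class TestSoilWater:
    def test_no_trigger_at_or_above_threshold(self, soil):
        pol = IrrigationPolicy(smc=0.25, v=5.0, enabled=True)
        _, irr, _ = soil_water_step(0.30, 0, 0, 1.0, soil, pol)
        assert irr == 0.0

    def test_irrigation_raises_moisture_by_v_over_root_depth(self):
        soil = SoilParams(root_depth=100.0)
        pol = IrrigationPolicy(smc=0.25, v=5.0, enabled=True)
        sm, irr, _ = soil_water_step(0.20, 0, 0, 0.0, soil, pol)
        assert irr == 5.0
        assert sm == pytest.approx(0.25)  # +0.05 from 5 cm over 100 cm

    def test_never_exceeds_saturation(self, soil):
        sm, _, _ = soil_water_step(0.40, 500.0, 0, 1.0, soil, IrrigationPolicy())
        assert sm <= soil.sm_sat

    def test_stress_clamped(self, soil):
        _, _, s_dry = soil_water_step(soil.sm_wilt * 0.6, 0, 0, 1.0, soil, IrrigationPolicy())
        _, _, s_wet = soil_water_step(soil.sm_fc, 0, 0, 1.0, soil, IrrigationPolicy())
        assert s_dry == 0.0
        assert s_wet == 1.0

    @settings(derandomize=True, deadline=None, max_examples=100)
    @given(
        sm=st.floats(0.07, 0.42),
        precip=st.floats(0, 80),
        et0=st.floats(0, 8),
        lai=st.floats(0, 8),
    )
    def test_bucket_bounds(self, sm, precip, et0, lai):
        soil = default_soil_params()
        pol = IrrigationPolicy(smc=0.21, v=4.0, enabled=True)
        sm2, _, stress = soil_water_step(sm, precip, et0, lai, soil, pol)
        assert 0.5 * soil.sm_wilt <= sm2 <= soil.sm_sat
        assert 0.0 <= stress <= 1.0


class TestDailyGrowth:
    state = (500.0, 400.0, 0.0, 300.0)

    def test_no_light_no_growth(self, crop):
        gross, inc, dlai = daily_growth(3.0, self.state, 0.0, 15.0, 0.5, 10.0, crop, 1.0)
        assert gross == 0.0
        assert all(v >= 0 for v in inc) and sum(inc) == 0.0

    def test_full_water_stress_stops_assimilation(self, crop):
        gross, _, _ = daily_growth(3.0, self.state, 20.0, 15.0, 0.5, 10.0, crop, 0.0)
        assert gross == 0.0

    def test_beer_law_saturation(self, crop):
        gross, _, _ = daily_growth(500.0, self.state, 20.0, 15.0, 0.5, 10.0, crop, 1.0)
        assert gross == pytest.approx(crop.eps_lue * 0.5 * 20.0, rel=1e-6)

    def test_gross_linear_in_light_use_efficiency(self, crop):
        """Respiration-free linearity: doubling eps_lue doubles assimilation."""
        lean = crop.evolve(rm_leaf=0.0, rm_stem=0.0, rm_storage=0.0, rm_root=0.0)
        g1, inc1, _ = daily_growth(2.0, self.state, 18.0, 12.0, 0.5, 10.0, lean, 0.8)
        g2, inc2, _ = daily_growth(
            2.0, self.state, 18.0, 12.0, 0.5, 10.0, lean.evolve(eps_lue=2 * lean.eps_lue), 0.8
        )
        assert g2 == pytest.approx(2 * g1, rel=1e-12)
        assert sum(inc2) == pytest.approx(2 * sum(inc1), rel=1e-12)


class TestSenescence:
    def test_leaf_dies_after_span_days_at_reference_temperature(self):
        cohorts = [[100.0, 0.0]]
        span = 10.0
        for day in range(1, 20):
            cohorts, living, died = senesce_leaves(cohorts, 35.0, span)
            if died:
                break
        assert day == span

    def test_half_rate_doubles_life_span(self):
        cohorts = [[100.0, 0.0]]
        span = 10.0
        for day in range(1, 50):
            cohorts, living, died = senesce_leaves(cohorts, 17.5, span)
            if died:
                break
        assert day == 2 * span

    def test_no_aging_below_zero(self):
        cohorts, living, died = senesce_leaves([[50.0, 5.0]], -10.0, 10.0)
        assert cohorts[0][1] == 5.0 and died == 0.0


class TestRunSeason:
    def test_anthesis_timing_under_constant_temperature(self, crop, soil):
        pw = constant_weather(10.0)
        s = run_season(pw, crop, soil, IrrigationPolicy(), date(2007, 10, 10))
        # TSUM1 = 1000 at 10 degC/day -> anthesis ~ day 100 after emergence
        assert (s.anthesis_date - date(2007, 10, 10)).days in (99, 100)
        # maturity after a further TSUM2/10 days
        assert (s.maturity_date - s.anthesis_date).days in (79, 80, 81)

    def test_zero_radiation_preserves_initial_aboveground_mass(self, crop, soil):
        pw = constant_weather(10.0, radiation=0.0)
        s = run_season(pw, crop, soil, IrrigationPolicy(), date(2007, 10, 10))
        initial_above = crop.tdwi * (1.0 - crop.part_root[0])
        assert s.final_agb == pytest.approx(initial_above, rel=1e-9)
        assert s.final_twso == 0.0

    def test_trajectories_respect_invariants(self, weather, crop, soil, policy, emergence):
        s = run_season(weather, crop, soil, policy, emergence)
        assert np.all(np.diff(s.agb) >= -1e-9)
        assert np.all(np.diff(s.dvs) >= 0)
        assert np.all(s.twso <= s.agb + 1e-9)
        assert np.all(s.sm <= soil.sm_sat + 1e-12)
        assert s.anthesis_date < s.maturity_date

    def test_deterministic_bit_identical(self, weather, crop, soil, policy, emergence):
        a = run_season(weather, crop, soil, policy, emergence)
        b = run_season(weather, crop, soil, policy, emergence)
        assert np.array_equal(a.agb, b.agb)
        assert np.array_equal(a.lai, b.lai)
        assert np.array_equal(a.sm, b.sm)

    def test_truncated_flag_when_weather_ends_early(self, crop, soil):
        pw = constant_weather(10.0, n_days=60)
        s = run_season(pw, crop, soil, IrrigationPolicy(), date(2007, 10, 10))
        assert s.truncated and s.maturity_date is None

    def test_no_irrigation_events_when_disabled(self, weather, crop, soil, emergence):
        s = run_season(weather, crop, soil, IrrigationPolicy(), emergence)
        assert s.irrigation == []

    def test_invalid_parameters_rejected(self, weather, soil, policy, emergence):
        bad = default_crop_params().evolve(tsum1=-5.0)
        with pytest.raises(ParameterError):
            run_season(weather, bad, soil, policy, emergence)

    def test_partition_table_validation(self):
        with pytest.raises(ParameterError):
            CropParams(part_leaf=(0.9, 0.34, 0.05, 0.0, 0.0)).validate()


class TestParamsConfig:
    def test_load_params_overrides_defaults(self, tmp_path):
        import yaml
        from wheatdas.crop_model import load_params

        path = tmp_path / "params.yaml"
        path.write_text(yaml.safe_dump({
            "crop": {"tsum1": 1100.0, "span": 28.0},
            "soil": {"sm_fc": 0.32},
            "irrigation": {"smc": 0.22, "v": 5.0, "enabled": True},
        }))
        crop, soil, policy = load_params(path)
        assert crop.tsum1 == 1100.0 and crop.span == 28.0
        assert crop.tsum2 == default_crop_params().tsum2  # untouched default
        assert soil.sm_fc == 0.32
        assert policy.v == 5.0 and policy.enabled

    def test_unknown_keys_rejected(self, tmp_path):
        import yaml
        from wheatdas.crop_model import load_params

        path = tmp_path / "bad.yaml"
        path.write_text(yaml.safe_dump({"crop": {"nonsense": 1}}))
        with pytest.raises(TypeError):
            load_params(path)
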