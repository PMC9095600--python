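"""Tests of the zonal parameterization and likelihood calibration layer."""

import math
from datetime import date

import numpy as np
import pytest
from scipy import stats

from wheatdas.calibration import (
    CalibrationProblem,
    CovarianceError,
    LikelihoodSpec,
    agb_from_yield,
    anthesis_from_heading,
    build_thiessen_zones,
    calibrate_crop_params,
    fit_phenology_params,
    gravimetric_to_volumetric,
    group_counties_by_yield,
    log_likelihood_term,
    total_log_likelihood,
    yield_to_dry_matter,
)
from wheatdas.crop_model import IrrigationPolicy, ParameterError, run_season
from .conftest import constant_weather


class TestThiessen:
    def test_nearest_and_tie_break(self):
        xy = np.array([[0.0, 0.0], [10.0, 0.0]])
        ids = np.array([1, 2])
        assigned = build_thiessen_zones(xy, ids, np.array([[2.0, 0.0], [5.0, 0.0]]))
        assert assigned[0] == 1  # strictly nearer
        assert assigned[1] == 1  # equidistant -> lowest id

    def test_matches_brute_force_on_random_cells(self):
        rng = np.random.default_rng(7)
        xy = rng.uniform(0, 100, (12, 2))
        ids = rng.permutation(np.arange(10, 22))
        cells = rng.uniform(0, 100, (100, 2))
        assigned = build_thiessen_zones(xy, ids, cells)
        for cell, got in zip(cells, assigned):
            d = np.hypot(*(xy - cell).T)
            best = min(zip(d, ids))  # (distance, id) lexicographic = tie-break by id
            assert got == best[1]

    def test_empty_station_list_rejected(self):
        with pytest.raises(ValueError):
            build_thiessen_zones(np.empty((0, 2)), np.array([]), np.array([[0.0, 0.0]]))


class TestSoilAndDateConversions:
    @pytest.mark.parametrize(
        "theta,bd,expected", [(0.20, 1.4, 0.28), (0.20, 1.0, 0.20)]
    )
    def test_gravimetric_to_volumetric(self, theta, bd, expected):
        assert gravimetric_to_volumetric(theta, bd) == pytest.approx(expected)

    def test_nonphysical_volumetric_content_rejected(self):
        with pytest.raises(ValueError):
            gravimetric_to_volumetric(0.8, 1.5)

    @pytest.mark.parametrize(
        "heading,expected",
        [
            (date(2009, 4, 20), date(2009, 4, 27)),
            (date(2009, 12, 28), date(2010, 1, 4)),
            (date(2008, 2, 25), date(2008, 3, 3)),  # leap year
        ],
    )
    def test_anthesis_seven_days_after_heading(self, heading, expected):
        assert anthesis_from_heading(heading) == expected


class TestPhenologyFit:
    def test_closed_form_under_constant_temperature(self):
        pw = constant_weather(10.0, n_days=300)
        em = date(2007, 10, 10)
        obs = [{
            "emergence": em,
            "anthesis": em.fromordinal(em.toordinal() + 100),
            "maturity": em.fromordinal(em.toordinal() + 180),
        }]
        t1, t2 = fit_phenology_params(obs, pw)
        assert t1 == pytest.approx(1000.0, abs=10.0)  # within one day of thermal time
        assert t2 == pytest.approx(800.0, abs=10.0)

    def test_recovers_simulator_phenology(self, crop, soil, weather, emergence):
        s = run_season(weather, crop, soil, IrrigationPolicy(), emergence)
        obs = [{"emergence": emergence, "anthesis": s.anthesis_date, "maturity": s.maturity_date}]
        t1, t2 = fit_phenology_params(obs, weather)
        assert abs(t1 - crop.tsum1) / crop.tsum1 < 0.02
        assert abs(t2 - crop.tsum2) / crop.tsum2 < 0.02

    def test_degenerate_phenology_rejected(self, weather):
        d = date(2008, 5, 1)
        with pytest.raises(ValueError):
            fit_phenology_params(
                [{"emergence": date(2007, 10, 10), "anthesis": d, "maturity": d}], weather
            )


class TestCountyGrouping:
    def test_worked_nine_county_example(self):
        ids = list(range(1, 10))
        yields = [9, 8, 7, 6, 5, 4, 3, 2, 1]  # already descending
        groups, reps, single = group_counties_by_yield(ids, yields)
        assert not single
        assert reps == {"high": 2, "medium": 5, "low": 8}  # yields 8, 5, 2
        assert groups["high"] == [1, 2, 3]
        assert groups["low"] == [7, 8, 9]

    def test_three_counties_each_their_own_representative(self):
        groups, reps, single = group_counties_by_yield(["a", "b", "c"], [1, 3, 2])
        assert not single
        assert reps == {"high": "b", "medium": "c", "low": "a"}

    def test_fallback_below_three_counties(self):
        groups, reps, single = group_counties_by_yield(["a", "b"], [5, 7])
        assert single
        assert reps["medium"] in ("a", "b")

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(3, 30))
            ids = list(range(n))
            yields = rng.uniform(1000, 9000, n).tolist()
            _, reps, _ = group_counties_by_yield(ids, yields)
            ranked = [i for _, i in sorted(zip(yields, ids), key=lambda t: -t[0])]
            for level, q in (("high", 0.17), ("medium", 0.50), ("low", 0.83)):
                assert reps[level] == ranked[int(math.floor(q * (n - 1) + 0.5))]


class TestYieldConversions:
    @pytest.mark.parametrize("fresh,dry", [(8000, 7000), (0, 0), (1000, 875)])
    def test_standard_moisture(self, fresh, dry):
        assert yield_to_dry_matter(fresh) == pytest.approx(dry)

    @pytest.mark.parametrize("dry,hi,agb", [(7000, 0.5, 14000), (7000, 1.0, 7000)])
    def test_harvest_index_conversion(self, dry, hi, agb):
        assert agb_from_yield(dry, hi) == pytest.approx(agb)

    def test_zero_harvest_index_rejected(self):
        with pytest.raises(ParameterError):
            agb_from_yield(7000, 0.0)


class TestLogLikelihood:
    def test_identity_covariance_at_mean(self):
        spec = LikelihoodSpec(x=np.zeros(3), mu=np.zeros(3), sigma=np.eye(3))
        assert log_likelihood_term(spec) == pytest.approx(-1.5 * math.log(2 * math.pi))
        assert log_likelihood_term(spec) == pytest.approx(-2.75682, abs=1e-5)

    def test_unit_offset(self):
        spec = LikelihoodSpec(x=np.ones(3), mu=np.zeros(3), sigma=np.eye(3))
        assert log_likelihood_term(spec) == pytest.approx(-2.75682 - 1.5, abs=1e-5)

    def test_decreases_with_distance(self):
        sigma = np.diag([1.0, 2.0, 3.0])
        vals = [
            log_likelihood_term(LikelihoodSpec(x=np.full(3, a), mu=np.zeros(3), sigma=sigma))
            for a in (0.0, 0.5, 1.0, 2.0)
        ]
        assert all(v1 > v2 for v1, v2 in zip(vals, vals[1:]))

    def test_matches_multivariate_normal_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            d = int(rng.integers(1, 6))
            a = rng.normal(size=(d, d))
            sigma = a @ a.T + d * np.eye(d)
            x, mu = rng.normal(size=d), rng.normal(size=d)
            ours = log_likelihood_term(LikelihoodSpec(x=x, mu=mu, sigma=sigma))
            ref = stats.multivariate_normal(mean=mu, cov=sigma).logpdf(x)
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_singular_covariance_rejected(self):
        with pytest.raises(CovarianceError):
            log_likelihood_term(
                LikelihoodSpec(x=np.zeros(2), mu=np.zeros(2), sigma=np.ones((2, 2)))
            )

    def test_total_is_sum_of_blocks(self):
        spec = LikelihoodSpec(x=np.zeros(3), mu=np.zeros(3), sigma=np.eye(3))
        total = total_log_likelihood(spec, spec, spec)
        assert total == pytest.approx(3 * log_likelihood_term(spec))
        assert total == pytest.approx(-8.27046, abs=1e-4)

    def test_mismatched_dimensions_rejected(self):
        s3 = LikelihoodSpec(x=np.zeros(3), mu=np.zeros(3), sigma=np.eye(3))
        s2 = LikelihoodSpec(x=np.zeros(2), mu=np.zeros(2), sigma=np.eye(2))
        with pytest.raises(ValueError):
            total_log_likelihood(s3, s3, s2)


class TestCalibrationContracts:
    def _problem(self, weather, soil, crop, policy, emergence):
        years = (2008,)
        s = run_season(weather, crop, soil, policy, emergence)
        return CalibrationProblem(
            weather=weather,
            emergence_dates={2008: emergence},
            soil=soil,
            base_params=crop,
            policies={2008: policy},
            dry_yields={2008: s.final_twso},
            harvest_index=s.final_twso / s.final_agb,
            years=years,
            lai_mu={2008: s.max_lai},
        )

    def test_zero_free_parameters_returns_input(self, weather, soil, crop, policy, emergence):
        prob = self._problem(weather, soil, crop, policy, emergence)
        params, obj = calibrate_crop_params(prob, free_params=())
        assert params is crop
        assert math.isfinite(obj)

    def test_result_respects_bounds(self, weather, soil, crop, policy, emergence):
        prob = self._problem(weather, soil, crop, policy, emergence)
        params, _ = calibrate_crop_params(prob, maxfev=150)
        from wheatdas.calibration import DEFAULT_PARAM_BOUNDS

        for name in ("tdwi", "span", "sla", "eps_lue"):
            lo, hi = DEFAULT_PARAM_BOUNDS[name]
            assert lo <= getattr(params, name) <= hi

    def test_missing_year_reduces_dimension(self, weather, soil, crop, policy, emergence):
        prob = self._problem(weather, soil, crop, policy, emergence)
        prob.years = (2008, 2009)  # 2009 has no county statistic
        assert prob.effective_years() == [2008]
        assert math.isfinite(prob.objective(crop))
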