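"""Synthetic study region: weather, stations, counties, truth and observations.

Generates a small, fully seeded stand-in for the real study inputs with
the statistical structure the pipeline assumes:

* smooth seasonal weather (sinusoidal temperature and radiation cycles
  with seeded daily noise, two-state precipitation occurrence) for a
  temperate winter-wheat climate — cold mid-winter, anthesis in spring,
  maturity in early summer;
* stations on a jittered lattice whose Thiessen zones partition the grid;
* per-zone, per-yield-level "truth" crop parameters with multiplicative
  level offsets, plus optional per-pixel perturbations of the emergence
  day, SPAN and TSUM1 (the quantities the assimilation layer recovers);
* county yield statistics as noisy aggregates of simulated truth (10%
  SD by default);
* station maximum-LAI observations drawn from the N(6.5, 1.5²) prior;
* satellite-like 8-day LAI per pixel: a low-biased (×0.7 by default),
  noisy, lightly smoothed subsample of the true daily LAI.

Every draw flows from one root seed through named substreams, so the
same scenario always regenerates bit-identical data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from wheatdas.assimilation import LAIObservationSeries
from wheatdas.calibration import STANDARD_MOISTURE, build_thiessen_zones
from wheatdas.crop_model import (
    CropParams,
    IrrigationPolicy,
    PreparedWeather,
    SeasonSeries,
    SoilParams,
    default_crop_params,
    default_soil_params,
    run_season,
)

__all__ = [
    "Region",
    "SyntheticObservations",
    "SyntheticScenario",
    "generate_region",
    "generate_weather",
    "simulate_truth_and_observe",
]

LEVELS = ("high", "medium", "low")


@dataclass
class SyntheticScenario:
    """Configuration of one synthetic study region."""

    seed: int = 0
    grid_shape: tuple[int, int] = (5, 5)
    cell_size: float = 1.0
    n_stations: int = 1
    counties_per_zone: int = 9
    years: tuple[int, ...] = (2008, 2009, 2010)  # harvest years
    sowing_month_day: tuple[int, int] = (10, 10)  # emergence, previous year
    mask_fraction: float = 0.8  # fraction of cells inside the wheat mask
    yield_sd_frac: float = 0.10  # county-yield noise
    lai_bias: float = 0.7  # multiplicative satellite-LAI bias
    lai_noise_sd: float = 0.10
    lai_smooth: bool = True  # 3-point moving average
    lai_cadence: int = 8  # days between satellite observations
    max_lai_prior: tuple[float, float] = (6.5, 1.5)
    # yield-level truth offsets (multiplicative unless noted)
    level_eps_lue: dict = field(
        default_factory=lambda: {"high": 1.15, "medium": 1.0, "low": 0.85}
    )
    level_tdwi: dict = field(
        default_factory=lambda: {"high": 1.10, "medium": 1.0, "low": 0.90}
    )
    level_span: dict = field(  # additive, days
        default_factory=lambda: {"high": 3.0, "medium": 0.0, "low": -3.0}
    )
    # per-pixel truth perturbations (ranges of uniform draws); zero = off
    pixel_idem_range: int = 6  # days
    pixel_span_range: float = 5.0  # days
    pixel_tsum1_rel_range: float = 0.10
    irrigation: IrrigationPolicy = field(
        default_factory=lambda: IrrigationPolicy(smc=0.21, v=4.0, enabled=True)
    )

    @classmethod
    def noise_free(cls, **overrides) -> "SyntheticScenario":
        """Scenario with every observation-noise source switched off."""
        kw = dict(
            yield_sd_frac=0.0,
            lai_bias=1.0,
            lai_noise_sd=0.0,
            lai_smooth=False,
            pixel_idem_range=0,
            pixel_span_range=0.0,
            pixel_tsum1_rel_range=0.0,
        )
        kw.update(overrides)
        return cls(**kw)

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, _stream_id(stream)])
        )

    def emergence_date(self, harvest_year: int) -> date:
        m, d = self.sowing_month_day
        return date(harvest_year - 1, m, d)


def _stream_id(stream: str) -> int:
    return int.from_bytes(stream.encode()[:4].ljust(4, b"\0"), "little")


# ---------------------------------------------------------------------------
# weather
# ---------------------------------------------------------------------------


def generate_weather(
    seed: int,
    start_date: date,
    n_days: int,
    mean_temp: float = 10.0,
    temp_amplitude: float = 14.0,
    temp_noise_sd: float = 2.0,
    diurnal_range: float = 9.0,
    rad_base: float = 16.0,
    rad_amplitude: float = 9.0,
    wet_prob: float = 0.25,
    wet_persistence: float = 0.5,
    mean_wet_precip: float = 5.0,
) -> pd.DataFrame:
    """Seeded daily weather with a sinusoidal annual cycle.

    Mean temperature follows ``mean_temp − temp_amplitude·cos(2π(doy−15)/365)``
    (coldest around mid-January) with Gaussian daily noise; radiation
    co-varies with day length; precipitation occurrence is a two-state
    chain with exponential wet-day amounts.
    """
    if n_days < 1:
        raise ValueError("n_days must be at least 1")
    rng = np.random.default_rng(seed)
    dates = pd.date_range(start_date, periods=n_days, freq="D")
    doy = dates.dayofyear.to_numpy(float)
    phase = 2.0 * math.pi * (doy - 15.0) / 365.0
    tmean = mean_temp - temp_amplitude * np.cos(phase)
    if temp_noise_sd > 0:
        tmean = tmean + rng.normal(0.0, temp_noise_sd, n_days)
    tmin = tmean - 0.5 * diurnal_range
    tmax = tmean + 0.5 * diurnal_range
    rad = rad_base - rad_amplitude * np.cos(phase)
    rad = np.maximum(1.0, rad + rng.normal(0.0, 1.0, n_days) * (temp_noise_sd > 0))

    wet = np.empty(n_days, bool)
    u = rng.random(n_days)
    wet[0] = u[0] < wet_prob
    for i in range(1, n_days):
        p = wet_persistence if wet[i - 1] else wet_prob
        wet[i] = u[i] < p
    precip = np.where(wet, rng.exponential(mean_wet_precip, n_days), 0.0)

    vap = np.clip(6.1 * np.exp(0.06 * tmean) * 0.7, 1.0, None)  # ~70% RH
    wind = np.full(n_days, 2.5)
    return pd.DataFrame(
        {
            "date": dates,
            "radiation": rad,
            "tmin": tmin,
            "tmax": tmax,
            "vap": vap,
            "wind": wind,
            "precip": precip,
        }
    )


# ---------------------------------------------------------------------------
# region
# ---------------------------------------------------------------------------


@dataclass
class Region:
    scenario: SyntheticScenario
    station_ids: np.ndarray
    station_xy: np.ndarray
    cell_zone: np.ndarray  # (rows, cols) station id per cell
    cell_county: np.ndarray  # (rows, cols) county id per cell
    county_zone: dict[int, int]
    county_province: dict[int, int]
    mask: np.ndarray  # (rows, cols) bool
    truth: dict[tuple[int, str], CropParams]  # (zone, level) -> params
    cell_level: np.ndarray  # (rows, cols) object: yield level per cell
    pixel_truth: dict[tuple[int, int], CropParams]
    pixel_idem_offset: dict[tuple[int, int], int]
    soil: SoilParams
    base_params: CropParams


def generate_region(scenario: SyntheticScenario) -> Region:
    """Stations, Thiessen zones, counties, mask and truth parameters."""
    rows, cols = scenario.grid_shape
    size = scenario.cell_size
    rng = scenario.rng("region")

    # cell centres
    yy, xx = np.mgrid[0:rows, 0:cols]
    cell_xy = np.column_stack([(xx.ravel() + 0.5) * size, (yy.ravel() + 0.5) * size])

    # stations on a jittered lattice
    k = scenario.n_stations
    side = max(1, int(math.ceil(math.sqrt(k))))
    sx, sy = [], []
    for i in range(k):
        gx = (i % side + 0.5) / side * cols * size
        gy = (i // side + 0.5) / side * rows * size
        sx.append(gx + rng.uniform(-0.2, 0.2) * size)
        sy.append(gy + rng.uniform(-0.2, 0.2) * size)
    station_xy = np.column_stack([sx, sy])
    station_ids = np.arange(1, k + 1)

    cell_zone = build_thiessen_zones(station_xy, station_ids, cell_xy).reshape(rows, cols)

    # counties: chunk each zone's cells (row-major order) into equal groups
    cell_county = np.zeros((rows, cols), int)
    county_zone: dict[int, int] = {}
    county_province: dict[int, int] = {}
    next_county = 1
    for zid in station_ids:
        flat = np.flatnonzero(cell_zone.ravel() == zid)
        n_counties = min(scenario.counties_per_zone, flat.size)
        chunks = np.array_split(flat, n_counties)
        for chunk in chunks:
            cell_county.ravel()[chunk] = next_county
            county_zone[next_county] = int(zid)
            county_province[next_county] = int(zid)  # one province per zone
            next_county += 1

    mask = rng.random((rows, cols)) < scenario.mask_fraction

    base = default_crop_params()
    soil = default_soil_params()
    truth: dict[tuple[int, str], CropParams] = {}
    for zid in station_ids:
        for level in LEVELS:
            truth[(int(zid), level)] = base.evolve(
                eps_lue=base.eps_lue * scenario.level_eps_lue[level],
                tdwi=base.tdwi * scenario.level_tdwi[level],
                span=base.span + scenario.level_span[level],
            )

    # yield level per county: deterministic rotation so every zone has all
    # three levels represented among its counties
    county_level: dict[int, str] = {}
    per_zone_counter: dict[int, int] = {}
    for cid, zid in county_zone.items():
        j = per_zone_counter.get(zid, 0)
        county_level[cid] = LEVELS[j % 3]
        per_zone_counter[zid] = j + 1

    cell_level = np.empty((rows, cols), object)
    pixel_truth: dict[tuple[int, int], CropParams] = {}
    pixel_idem: dict[tuple[int, int], int] = {}
    prng = scenario.rng("pixels")
    for r in range(rows):
        for c in range(cols):
            cid = int(cell_county[r, c])
            zid = int(cell_zone[r, c])
            level = county_level[cid]
            cell_level[r, c] = level
            params = truth[(zid, level)]
            d_idem = 0
            if scenario.pixel_idem_range > 0:
                d_idem = int(
                    prng.integers(-scenario.pixel_idem_range, scenario.pixel_idem_range + 1)
                )
            d_span = (
                prng.uniform(-scenario.pixel_span_range, scenario.pixel_span_range)
                if scenario.pixel_span_range > 0
                else 0.0
            )
            d_t1 = (
                prng.uniform(-scenario.pixel_tsum1_rel_range, scenario.pixel_tsum1_rel_range)
                if scenario.pixel_tsum1_rel_range > 0
                else 0.0
            )
            pixel_truth[(r, c)] = params.evolve(
                span=max(10.0, params.span + d_span),
                tsum1=params.tsum1 * (1.0 + d_t1),
            )
            pixel_idem[(r, c)] = d_idem

    return Region(
        scenario=scenario,
        station_ids=station_ids,
        station_xy=station_xy,
        cell_zone=cell_zone,
        cell_county=cell_county,
        county_zone=county_zone,
        county_province=county_province,
        mask=mask,
        truth=truth,
        cell_level=cell_level,
        pixel_truth=pixel_truth,
        pixel_idem_offset=pixel_idem,
        soil=soil,
        base_params=base,
    )


# ---------------------------------------------------------------------------
# truth simulation and observation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticObservations:
    weather: PreparedWeather
    station_obs: pd.DataFrame  # station phenology + max-LAI draws
    county_stats: pd.DataFrame  # county, province, year, fresh yield
    harvest_index: dict[int, float]  # province -> HI
    county_harvest_index: dict[int, float]  # county -> its own simulated ratio
    county_hi_by_year: dict[tuple[int, int], float]  # (county, year) -> ratio
    pixel_lai: dict[tuple[int, int, int], LAIObservationSeries]  # (r, c, year)
    pixel_series: dict[tuple[int, int, int], SeasonSeries]  # truth trajectories
    group_truth_agb: dict[tuple[int, str, int], float]  # (zone, level, year)
    group_truth_maxlai: dict[tuple[int, str, int], float]


def region_weather(scenario: SyntheticScenario) -> pd.DataFrame:
    """One weather series covering all study seasons (shared by the region)."""
    first = min(scenario.years)
    last = max(scenario.years)
    start = date(first - 1, 9, 1)
    n_days = (date(last, 8, 31) - start).days + 1
    return generate_weather(int(scenario.rng("weather").integers(2**31)), start, n_days)


def simulate_truth_and_observe(
    region: Region,
    weather: pd.DataFrame | PreparedWeather | None = None,
    scenario: SyntheticScenario | None = None,
) -> SyntheticObservations:
    """Run the truth simulations and derive every synthetic observation."""
    scenario = scenario or region.scenario
    if weather is None:
        weather = region_weather(scenario)
    pw = weather if isinstance(weather, PreparedWeather) else PreparedWeather(weather)
    rng = scenario.rng("observe")
    policy = scenario.irrigation
    soil = region.soil
    rows, cols = scenario.grid_shape

    # truth per (zone, level, year) at the zonal emergence date
    group_runs: dict[tuple[int, str, int], SeasonSeries] = {}
    for (zid, level), params in region.truth.items():
        for year in scenario.years:
            group_runs[(zid, level, year)] = run_season(
                pw, params, soil, policy, scenario.emergence_date(year)
            )

    # provincial harvest index from the truth runs (mean TWSO/AGB ratio)
    harvest_index: dict[int, float] = {}
    for zid in region.station_ids:
        ratios = [
            group_runs[(int(zid), lvl, y)].final_twso
            / group_runs[(int(zid), lvl, y)].final_agb
            for lvl in LEVELS
            for y in scenario.years
        ]
        harvest_index[int(zid)] = float(np.mean(ratios))

    # per-pixel truth runs (perturbed parameters and emergence day)
    pixel_series: dict[tuple[int, int, int], SeasonSeries] = {}
    pixel_lai: dict[tuple[int, int, int], LAIObservationSeries] = {}
    for (r, c), params in region.pixel_truth.items():
        if not region.mask[r, c]:
            continue
        d_idem = region.pixel_idem_offset[(r, c)]
        for year in scenario.years:
            em = scenario.emergence_date(year) + timedelta(days=d_idem)
            s = run_season(pw, params, soil, policy, em)
            pixel_series[(r, c, year)] = s
            pixel_lai[(r, c, year)] = _satellite_lai(s, scenario, rng)

    # county statistics: noisy aggregates of simulated truth yields
    stats_rows = []
    county_hi_parts: dict[int, list] = {}
    county_hi_by_year: dict[tuple[int, int], float] = {}
    for year in scenario.years:
        for cid, zid in region.county_zone.items():
            cells = [
                (r, c)
                for r in range(rows)
                for c in range(cols)
                if region.cell_county[r, c] == cid and region.mask[r, c]
            ]
            twso = [
                pixel_series[(r, c, year)].final_twso
                for (r, c) in cells
                if (r, c, year) in pixel_series
            ]
            if not twso:
                continue
            agb = [
                pixel_series[(r, c, year)].final_agb
                for (r, c) in cells
                if (r, c, year) in pixel_series
            ]
            ratio = float(np.mean(twso)) / float(np.mean(agb))
            county_hi_parts.setdefault(cid, []).append(ratio)
            county_hi_by_year[(cid, year)] = ratio
            dry = float(np.mean(twso))
            fresh = dry / (1.0 - STANDARD_MOISTURE)
            if scenario.yield_sd_frac > 0:
                fresh *= 1.0 + rng.normal(0.0, scenario.yield_sd_frac)
            stats_rows.append(
                {
                    "county": cid,
                    "province": region.county_province[cid],
                    "year": year,
                    "yield_fresh": fresh,
                }
            )
    county_stats = pd.DataFrame(stats_rows)

    # station observations: phenology from the zonal medium run; max-LAI
    # drawn from the observed-histogram prior
    st_rows = []
    mu, sd = scenario.max_lai_prior
    for zid in region.station_ids:
        for year in scenario.years:
            s = group_runs[(int(zid), "medium", year)]
            st_rows.append(
                {
                    "station": int(zid),
                    "year": year,
                    "emergence": scenario.emergence_date(year),
                    "anthesis": s.anthesis_date,
                    "maturity": s.maturity_date,
                    "max_lai_obs": float(rng.normal(mu, sd)),
                }
            )
    station_obs = pd.DataFrame(st_rows)

    group_truth_agb = {
        key: run.final_agb for key, run in group_runs.items()
    }
    group_truth_maxlai = {key: run.max_lai for key, run in group_runs.items()}
    return SyntheticObservations(
        weather=pw,
        station_obs=station_obs,
        county_stats=county_stats,
        harvest_index=harvest_index,
        county_harvest_index={
            cid: float(np.mean(parts)) for cid, parts in county_hi_parts.items()
        },
        county_hi_by_year=county_hi_by_year,
        pixel_lai=pixel_lai,
        pixel_series=pixel_series,
        group_truth_agb=group_truth_agb,
        group_truth_maxlai=group_truth_maxlai,
    )


def _satellite_lai(
    series: SeasonSeries, scenario: SyntheticScenario, rng: np.random.Generator
) -> LAIObservationSeries:
    """Subsample, bias, perturb and smooth a true daily LAI trajectory."""
    idx = np.arange(0, series.n_days, scenario.lai_cadence)
    dates = series.dates[idx]
    values = series.lai[idx] * scenario.lai_bias
    if scenario.lai_noise_sd > 0:
        values = values + rng.normal(0.0, scenario.lai_noise_sd, values.size)
    if scenario.lai_smooth and values.size >= 3:
        kernel = np.array([1.0, 1.0, 1.0]) / 3.0
        inner = np.convolve(values, kernel, mode="valid")
        values = np.concatenate([[values[0]], inner, [values[-1]]])
    values = np.maximum(values, 0.0)
    return LAIObservationSeries(dates=dates, values=values)
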