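"""Zonal parameterization and likelihood-based calibration.

Implements the zonal layer of the pipeline: Thiessen (nearest-station)
assignment of grid cells to agro-meteorological stations, soil-constant
conversion, phenology-parameter fitting (TSUM1/TSUM2), county yield-level
grouping, and the three-step maximum-likelihood calibration of crop and
irrigation parameters against county yield statistics and the station
maximum-LAI distribution.

The objective is a multivariate Gaussian log-likelihood over three blocks
— annual maximum LAI, storage-organ biomass (grain yield) and aboveground
biomass at maturity — each with independent years (diagonal covariance by
default):

    log L_block = −½ [ d·log(2π) + log|Σ| + (x−μ)ᵀ Σ⁻¹ (x−μ) ]
    log L       = log L_LAI + log L_TWSO + log L_AGB

with d the number of jointly calibrated years (3 by default).  The
maximum-LAI block uses the station-derived prior N(6.5, 1.5²) per year;
the yield and biomass blocks use county statistics with a standard
deviation of 10% of each statistical value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from wheatdas._optim import nelder_mead
from wheatdas.crop_model import (
    CropParams,
    IrrigationPolicy,
    ParameterError,
    PreparedWeather,
    SoilParams,
    crossing_day,
    run_season,
)

__all__ = [
    "CalibrationProblem",
    "CalibrationResult",
    "CovarianceError",
    "LikelihoodSpec",
    "MAX_LAI_PRIOR_MEAN",
    "MAX_LAI_PRIOR_SD",
    "STANDARD_MOISTURE",
    "YIELD_SD_FRACTION",
    "agb_from_yield",
    "anthesis_from_heading",
    "build_thiessen_zones",
    "calibrate_crop_params",
    "calibrate_irrigation",
    "fit_phenology_params",
    "gravimetric_to_volumetric",
    "group_counties_by_yield",
    "log_likelihood_term",
    "three_step_calibration",
    "total_log_likelihood",
    "yield_to_dry_matter",
]

#: standard grain moisture content used to convert fresh to dry yield
STANDARD_MOISTURE = 0.125
#: station maximum-LAI prior (per-year mean and SD of the observed histogram)
MAX_LAI_PRIOR_MEAN = 6.5
MAX_LAI_PRIOR_SD = 1.5
#: observation SD as a fraction of each county statistical value
YIELD_SD_FRACTION = 0.10


class CovarianceError(ValueError):
    """Covariance matrix is not symmetric positive-definite."""


# ---------------------------------------------------------------------------
# zonal parameterization
# ---------------------------------------------------------------------------


def build_thiessen_zones(
    station_xy: np.ndarray, station_ids: np.ndarray, cell_xy: np.ndarray
) -> np.ndarray:
    """Assign each cell to its nearest station (Thiessen zones).

    Ties are broken toward the lowest station id.  Returns the station id
    for every cell.
    """
    station_xy = np.asarray(station_xy, float)
    cell_xy = np.asarray(cell_xy, float)
    station_ids = np.asarray(station_ids)
    if station_xy.ndim != 2 or station_xy.shape[0] == 0:
        raise ValueError("at least one station with (x, y) coordinates required")
    order = np.argsort(station_ids, kind="stable")
    xy = station_xy[order]
    ids = station_ids[order]
    d2 = ((cell_xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
    # argmin returns the first minimum, i.e. the lowest id after sorting
    return ids[np.argmin(d2, axis=1)]


def gravimetric_to_volumetric(theta_g: float, bulk_density: float) -> float:
    """Convert gravimetric water content to volumetric via bulk density."""
    if not (0.0 < theta_g < 1.0):
        raise ValueError("gravimetric water content must lie in (0, 1)")
    if bulk_density <= 0:
        raise ValueError("bulk density must be positive")
    theta_v = theta_g * bulk_density
    if theta_v >= 1.0:
        raise ValueError(
            f"volumetric water content {theta_v:.3f} >= 1: inconsistent soil data"
        )
    return theta_v


def anthesis_from_heading(heading_date: date) -> date:
    """Anthesis estimated as the observed heading date plus seven days."""
    return heading_date + timedelta(days=7)


def fit_phenology_params(
    observations: list[dict],
    weather: pd.DataFrame | PreparedWeather,
    tbase: float = 0.0,
    start: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Fit (TSUM1, TSUM2) from observed emergence/anthesis/maturity dates.

    Each observation is a mapping with ``emergence``, ``anthesis`` and
    ``maturity`` dates.  The simulated anthesis and maturity days are the
    (fractionally interpolated) days where cumulative thermal time from
    emergence crosses TSUM1 and TSUM1+TSUM2; the fit minimizes the sum of
    squared day errors across years with a derivative-free simplex search
    started from the closed-form single-year thermal sums.
    """
    pw = weather if isinstance(weather, PreparedWeather) else PreparedWeather(weather)
    seasons = []
    t1_guess, t2_guess = [], []
    for obs in observations:
        em, anth, mat = obs["emergence"], obs["anthesis"], obs["maturity"]
        if not (em < anth < mat):
            raise ValueError("degenerate phenology: require emergence < anthesis < maturity")
        i0 = pw.index_of(em)
        n = (mat - em).days + 30
        if i0 + n > pw.dates.size:
            n = pw.dates.size - i0
        if (mat - em).days >= n:
            raise ValueError("weather series does not cover the observed season")
        cum = np.cumsum(np.maximum(0.0, pw.tmean[i0 : i0 + n] - tbase))
        d_anth = float((anth - em).days)
        d_mat = float((mat - em).days)
        seasons.append((cum, d_anth, d_mat))
        t1_guess.append(cum[int(d_anth) - 1])
        t2_guess.append(cum[int(d_mat) - 1] - cum[int(d_anth) - 1])

    if start is None:
        start = (float(np.mean(t1_guess)), float(np.mean(t2_guess)))

    def objective(x):
        t1, t2 = x
        if t1 <= 0 or t2 <= 0:
            return 1e12
        sse = 0.0
        for cum, d_anth, d_mat in seasons:
            sa = crossing_day(cum, t1)
            sm = crossing_day(cum, t1 + t2)
            if not (math.isfinite(sa) and math.isfinite(sm)):
                return 1e12
            sse += (sa - d_anth) ** 2 + (sm - d_mat) ** 2
        return sse

    res = nelder_mead(objective, np.array(start), bounds=[(50.0, 4000.0)] * 2)
    return float(res.x[0]), float(res.x[1])


def group_counties_by_yield(
    county_ids: list, mean_yields: list[float]
) -> tuple[dict[str, list], dict[str, object], bool]:
    """Split a zone's counties into high/medium/low yield groups.

    Counties are ranked by descending mean yield and split at the 33% and
    67% quantiles of the ranked order; the representative county of each
    group sits at position round(q·(n−1)) (half-up) of the descending list
    for q in {0.17, 0.50, 0.83}.  With fewer than three counties the zone
    falls back to a single group represented by the median county (the
    returned flag is True).
    """
    ids = list(county_ids)
    yields = np.asarray(mean_yields, float)
    if len(ids) != yields.size:
        raise ValueError("county ids and yields must have equal length")
    order = np.argsort(-yields, kind="stable")
    ranked = [ids[i] for i in order]
    n = len(ranked)

    def pos(q: float) -> int:
        return int(math.floor(q * (n - 1) + 0.5))

    if n < 3:
        median = ranked[pos(0.50)]
        groups = {"high": [], "medium": list(ranked), "low": []}
        reps = {"high": median, "medium": median, "low": median}
        return groups, reps, True

    cut1 = 0.33 * (n - 1)
    cut2 = 0.67 * (n - 1)
    groups = {"high": [], "medium": [], "low": []}
    for i, cid in enumerate(ranked):
        if i <= cut1:
            groups["high"].append(cid)
        elif i <= cut2:
            groups["medium"].append(cid)
        else:
            groups["low"].append(cid)
    reps = {
        "high": ranked[pos(0.17)],
        "medium": ranked[pos(0.50)],
        "low": ranked[pos(0.83)],
    }
    return groups, reps, False


def yield_to_dry_matter(fresh_yield: float) -> float:
    """Convert fresh-basis yield to dry matter at 12.5% standard moisture."""
    if fresh_yield < 0:
        raise ValueError("yield must be non-negative")
    return fresh_yield * (1.0 - STANDARD_MOISTURE)


def agb_from_yield(dry_yield: float, harvest_index: float) -> float:
    """Convert dry grain yield to aboveground biomass via the harvest index."""
    if not (0.0 < harvest_index <= 1.0):
        raise ParameterError("harvest index must lie in (0, 1]")
    return dry_yield / harvest_index


# ---------------------------------------------------------------------------
# log-likelihood
# ---------------------------------------------------------------------------


@dataclass
class LikelihoodSpec:
    """One Gaussian block: simulated vector x, observation mean μ, covariance Σ."""

    x: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        self.x = np.atleast_1d(np.asarray(self.x, float))
        self.mu = np.atleast_1d(np.asarray(self.mu, float))
        self.sigma = np.atleast_2d(np.asarray(self.sigma, float))
        d = self.x.size
        if self.mu.size != d or self.sigma.shape != (d, d):
            raise ValueError("x, mu and sigma dimensions must agree")

    @property
    def d(self) -> int:
        return int(self.x.size)

    @classmethod
    def diagonal(cls, x, mu, sd) -> "LikelihoodSpec":
        sd = np.broadcast_to(np.asarray(sd, float), np.atleast_1d(x).shape)
        return cls(x=x, mu=mu, sigma=np.diag(sd**2))


def log_likelihood_term(spec: LikelihoodSpec) -> float:
    """Gaussian log-likelihood −½[d·log 2π + log|Σ| + MD²] of one block.

    MD is the Mahalanobis distance of x from μ under Σ; Σ must be
    symmetric positive-definite.
    """
    if not np.allclose(spec.sigma, spec.sigma.T, atol=1e-12):
        raise CovarianceError("covariance must be symmetric")
    try:
        c, low = cho_factor(spec.sigma, lower=True)
    except LinAlgError as exc:
        raise CovarianceError("covariance is not positive-definite") from exc
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    diff = spec.x - spec.mu
    md2 = float(diff @ cho_solve((c, low), diff))
    return -0.5 * (spec.d * math.log(2.0 * math.pi) + logdet + md2)


def total_log_likelihood(
    lai_spec: LikelihoodSpec, twso_spec: LikelihoodSpec, agb_spec: LikelihoodSpec
) -> float:
    """Sum of the LAI, TWSO and AGB block log-likelihoods (shared d)."""
    if not (lai_spec.d == twso_spec.d == agb_spec.d):
        raise ValueError("all three likelihood blocks must share the same d")
    return (
        log_likelihood_term(lai_spec)
        + log_likelihood_term(twso_spec)
        + log_likelihood_term(agb_spec)
    )


# ---------------------------------------------------------------------------
# three-step calibration
# ---------------------------------------------------------------------------

DEFAULT_FREE_PARAMS = ("tdwi", "span", "sla", "eps_lue")

DEFAULT_PARAM_BOUNDS = {
    "tdwi": (20.0, 300.0),
    "span": (15.0, 45.0),
    "sla": (0.0012, 0.0035),
    "eps_lue": (10.0, 60.0),
    "tsum1": (600.0, 1600.0),
    "tsum2": (400.0, 1200.0),
    "rgrlai": (0.004, 0.015),
    "k_ext": (0.4, 0.8),
}


@dataclass
class CalibrationProblem:
    """Inputs for calibrating one yield-level group of one zone.

    ``dry_yields`` maps each calibration year to the representative
    county's statistical yield converted to dry matter (kg·ha⁻¹); the AGB
    observation is derived from it through the provincial harvest index.
    """

    weather: PreparedWeather
    emergence_dates: dict[int, date]
    soil: SoilParams
    base_params: CropParams
    policies: dict[int, IrrigationPolicy]
    dry_yields: dict[int, float]
    harvest_index: float | dict[int, float]  # provincial scalar or per-year
    years: tuple[int, ...]
    lai_prior: tuple[float, float] = (MAX_LAI_PRIOR_MEAN, MAX_LAI_PRIOR_SD)
    #: optional per-year max-LAI observation means; when absent every year
    #: uses the station-histogram prior mean
    lai_mu: dict[int, float] | None = None
    sd_fraction: float = YIELD_SD_FRACTION
    max_days: int = 330

    def effective_years(self) -> list[int]:
        # years missing a county statistic are dropped (d reduced)
        return [y for y in self.years if y in self.dry_yields]

    def objective(
        self,
        crop: CropParams,
        policies: dict[int, IrrigationPolicy] | None = None,
    ) -> float:
        """Total log-likelihood of one candidate parameterization."""
        policies = self.policies if policies is None else policies
        years = self.effective_years()
        if not years:
            raise ValueError("no calibration years with county statistics")
        sim_lai, sim_twso, sim_agb = [], [], []
        for y in years:
            try:
                s = run_season(
                    self.weather,
                    crop,
                    self.soil,
                    policies[y],
                    self.emergence_dates[y],
                    max_days=self.max_days,
                )
            except Exception:
                return -np.inf
            sim_lai.append(s.max_lai)
            sim_twso.append(s.final_twso)
            sim_agb.append(s.final_agb)
        mu_twso = np.array([self.dry_yields[y] for y in years])
        if isinstance(self.harvest_index, dict):
            hi = np.array([self.harvest_index[y] for y in years])
        else:
            hi = self.harvest_index
        mu_agb = mu_twso / hi
        if self.lai_mu is not None:
            mu_lai = [self.lai_mu[y] for y in years]
        else:
            mu_lai = [self.lai_prior[0]] * len(years)
        lai_spec = LikelihoodSpec.diagonal(sim_lai, mu_lai, self.lai_prior[1])
        twso_spec = LikelihoodSpec.diagonal(sim_twso, mu_twso, self.sd_fraction * mu_twso)
        agb_spec = LikelihoodSpec.diagonal(sim_agb, mu_agb, self.sd_fraction * mu_agb)
        return total_log_likelihood(lai_spec, twso_spec, agb_spec)


@dataclass
class CalibrationResult:
    params: CropParams
    policies: dict[int, IrrigationPolicy]
    objectives: list[float] = field(default_factory=list)  # one per step

    @property
    def final_objective(self) -> float:
        return self.objectives[-1]


def calibrate_crop_params(
    problem: CalibrationProblem,
    free_params: tuple[str, ...] = DEFAULT_FREE_PARAMS,
    bounds: dict[str, tuple[float, float]] | None = None,
    policies: dict[int, IrrigationPolicy] | None = None,
    maxfev: int = 2000,
) -> tuple[CropParams, float]:
    """Step 1 (and 3): maximize the log-likelihood over the free crop
    parameters with irrigation fixed.  Returns (params, objective); if the
    search cannot improve on the starting point the start is returned."""
    bounds = {**DEFAULT_PARAM_BOUNDS, **(bounds or {})}
    base = problem.base_params
    start_obj = problem.objective(base, policies)
    if not free_params:
        return base, start_obj
    x0 = np.array([getattr(base, p) for p in free_params])
    bnds = [bounds[p] for p in free_params]
    lo = np.array([b[0] for b in bnds])
    hi = np.array([b[1] for b in bnds])

    def neg(x):
        crop = base.evolve(**dict(zip(free_params, x)))
        return -problem.objective(crop, policies)

    # deterministic multi-start: the configured start plus two scaled
    # variants, to step off compensation ridges (e.g. TDWI x SPAN)
    best = None
    for scale in (1.0, 0.9, 1.1):
        res = nelder_mead(neg, np.clip(scale * x0, lo, hi), bounds=bnds, maxfev=maxfev)
        if best is None or res.fun < best.fun:
            best = res
    if -best.fun <= start_obj:
        return base, start_obj
    return base.evolve(**dict(zip(free_params, best.x))), float(-best.fun)


def calibrate_irrigation(
    problem: CalibrationProblem,
    crop: CropParams,
    v_max: float = 10.0,
    maxfev: int = 2000,
) -> tuple[dict[int, IrrigationPolicy], float]:
    """Step 2: maximize the same objective over the per-year irrigation
    pair (SMc, V) — six parameters for a three-year window — with the crop
    parameters held fixed."""
    years = problem.effective_years()
    soil = problem.soil
    x0, bnds = [], []
    for y in years:
        p = problem.policies.get(y, IrrigationPolicy())
        smc0 = p.smc if soil.sm_wilt <= p.smc <= soil.sm_fc else soil.sm_crit
        x0 += [smc0, p.v]
        bnds += [(soil.sm_wilt, soil.sm_fc), (0.0, v_max)]

    def unpack(x) -> dict[int, IrrigationPolicy]:
        return {
            y: IrrigationPolicy(smc=x[2 * i], v=x[2 * i + 1], enabled=True)
            for i, y in enumerate(years)
        }

    incumbent_obj = problem.objective(crop)
    start_obj = problem.objective(crop, unpack(np.array(x0)))

    def neg(x):
        return -problem.objective(crop, unpack(x))

    res = nelder_mead(neg, np.array(x0), bounds=bnds, maxfev=maxfev)
    best = max(start_obj, float(-res.fun))
    if best <= incumbent_obj:
        return problem.policies, incumbent_obj
    if -res.fun <= start_obj:
        return unpack(np.array(x0)), start_obj
    return unpack(res.x), float(-res.fun)


def three_step_calibration(
    problem: CalibrationProblem,
    free_params: tuple[str, ...] = DEFAULT_FREE_PARAMS,
    bounds: dict[str, tuple[float, float]] | None = None,
    maxfev: int = 2000,
) -> CalibrationResult:
    """Crop-parameter fit → irrigation fit → crop-parameter re-fit.

    Each step starts from the incumbent solution, so the objective
    sequence is non-decreasing up to optimizer tolerance.
    """
    params1, obj1 = calibrate_crop_params(
        problem, free_params, bounds, maxfev=maxfev
    )
    problem1 = replace(problem, base_params=params1)
    policies2, obj2 = calibrate_irrigation(problem1, params1, maxfev=maxfev)
    problem2 = replace(problem1, policies=policies2)
    params3, obj3 = calibrate_crop_params(
        problem2, free_params, bounds, policies=policies2, maxfev=maxfev
    )
    return CalibrationResult(
        params=params3, policies=policies2, objectives=[obj1, obj2, obj3]
    )
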