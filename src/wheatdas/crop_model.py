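"""Reduced-form WOFOST-style daily winter-wheat simulator.

Simulates phenology (thermal time), leaf-area dynamics with cohort-based
senescence, light-use-efficiency biomass accumulation with maintenance
respiration, and a single-layer soil water bucket with threshold-triggered
irrigation.  State variables mirror the classic crop-model quartet: DVS
(development stage, 0 = emergence, 1 = anthesis, 2 = maturity), LAI,
aboveground biomass (AGB, living + dead aboveground organs) and storage
organ biomass (TWSO, i.e. grain yield), all at a daily time step.

The simulator deliberately trades process detail (photosynthesis-light
response curves, vernalization, photoperiod, nutrient limitation) for a
small, fast, fully documented core that exposes exactly the parameters the
calibration and assimilation layers operate on: TSUM1, TSUM2, TDWI, SPAN,
the irrigation pair (SMc, V) and the emergence day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

__all__ = [
    "CropParams",
    "IrrigationPolicy",
    "SeasonSeries",
    "SoilParams",
    "WeatherError",
    "ParameterError",
    "daily_growth",
    "default_crop_params",
    "default_soil_params",
    "load_weather",
    "run_season",
    "senesce_leaves",
    "soil_water_step",
    "thermal_increment",
    "update_phenology",
]

LEAF_AGE_REF_TEMP = 35.0  # °C; SPAN is the leaf life span at this temperature

WEATHER_COLUMNS = ["date", "radiation", "tmin", "tmax", "vap", "wind", "precip"]


class WeatherError(ValueError):
    """Invalid or insufficient weather input."""


class ParameterError(ValueError):
    """A crop, soil or irrigation parameter violates its contract."""


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CropParams:
    """Biological constants of the reduced-form winter-wheat core.

    Units: TSUM1/TSUM2 °C·d; TDWI kg·ha⁻¹; SPAN d (at 35 °C); SLA ha·kg⁻¹;
    RGRLAI (°C·d)⁻¹; eps_lue kg·ha⁻¹ dry matter per MJ·m⁻² intercepted PAR;
    rm coefficients d⁻¹ at 25 °C.
    """

    tsum1: float = 1000.0
    tsum2: float = 800.0
    tdwi: float = 80.0
    span: float = 30.0
    sla: float = 0.0019
    rgrlai: float = 0.0082
    k_ext: float = 0.60
    eps_lue: float = 30.0
    rm_leaf: float = 0.022
    rm_stem: float = 0.012
    rm_storage: float = 0.010
    rm_root: float = 0.010
    q10: float = 2.0
    tbase_pheno: float = 0.0
    dvs_juvenile: float = 0.3
    # self-shading mortality: LAI above lai_crit decays toward it
    lai_crit: float = 6.0
    shade_death_rate: float = 0.05  # d⁻¹ applied to the excess LAI
    # piecewise-linear partitioning of net growth vs. DVS
    part_dvs: tuple = (0.0, 0.65, 0.95, 1.2, 2.0)
    part_leaf: tuple = (0.40, 0.34, 0.05, 0.00, 0.00)
    part_stem: tuple = (0.25, 0.44, 0.25, 0.00, 0.00)
    part_storage: tuple = (0.00, 0.00, 0.65, 1.00, 1.00)
    part_root: tuple = (0.35, 0.22, 0.05, 0.00, 0.00)

    def validate(self) -> None:
        if not (self.tsum1 > 0 and self.tsum2 > 0):
            raise ParameterError("TSUM1 and TSUM2 must be positive")
        if self.span <= 0:
            raise ParameterError("SPAN must be positive")
        for name in ("tdwi", "sla", "rgrlai", "k_ext", "eps_lue", "q10"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        nodes = np.asarray(self.part_dvs)
        fracs = np.vstack(
            [self.part_leaf, self.part_stem, self.part_storage, self.part_root]
        )
        if fracs.shape[1] != nodes.size:
            raise ParameterError("partition table columns must match DVS nodes")
        if np.any(fracs < 0) or np.any(fracs > 1):
            raise ParameterError("partition fractions must lie in [0, 1]")
        if not np.allclose(fracs.sum(axis=0), 1.0, atol=1e-9):
            raise ParameterError("partition fractions must sum to 1 at each node")

    def evolve(self, **changes) -> "CropParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class SoilParams:
    """Single-layer bucket soil: volumetric moisture constants and rooting depth."""

    sm_wilt: float = 0.12
    sm_fc: float = 0.30
    sm_sat: float = 0.42
    root_depth: float = 100.0  # cm
    sm_crit_frac: float = 0.5  # stress onset between wilting point and field capacity

    def validate(self) -> None:
        if not (0.0 < self.sm_wilt < self.sm_fc < self.sm_sat < 1.0):
            raise ParameterError("require 0 < sm_wilt < sm_fc < sm_sat < 1")
        if self.root_depth <= 0:
            raise ParameterError("root_depth must be positive")
        if not (0.0 < self.sm_crit_frac <= 1.0):
            raise ParameterError("sm_crit_frac must lie in (0, 1]")

    @property
    def sm_crit(self) -> float:
        return self.sm_wilt + self.sm_crit_frac * (self.sm_fc - self.sm_wilt)


@dataclass(frozen=True)
class IrrigationPolicy:
    """Threshold-triggered irrigation: when soil moisture drops below the
    critical value SMc at the start of a day, V cm of water is applied."""

    smc: float = 0.0
    v: float = 0.0  # cm per event
    enabled: bool = False

    def validate(self, soil: SoilParams | None = None) -> None:
        if self.v < 0:
            raise ParameterError("irrigation amount V must be non-negative")
        if self.enabled and soil is not None:
            if not (soil.sm_wilt <= self.smc <= soil.sm_sat):
                raise ParameterError("SMc must lie within [sm_wilt, sm_sat]")


def default_crop_params() -> CropParams:
    """Documented winter-wheat defaults; every field is overridable."""
    return CropParams()


def default_soil_params() -> SoilParams:
    return SoilParams()


# ---------------------------------------------------------------------------
# elementary process kernels
# ---------------------------------------------------------------------------


def thermal_increment(tmin: float, tmax: float, tbase: float) -> float:
    """Daily thermal time, max(0, (tmin + tmax)/2 − tbase), in °C·d."""
    if not (math.isfinite(tmin) and math.isfinite(tmax) and math.isfinite(tbase)):
        raise WeatherError("non-finite temperature input")
    if tmin > tmax:
        raise WeatherError(f"tmin {tmin} exceeds tmax {tmax}")
    return max(0.0, 0.5 * (tmin + tmax) - tbase)


def update_phenology(tsum_accum: float, increment: float, tsum1: float, tsum2: float) -> tuple[float, float]:
    """Advance accumulated thermal time and return (new_tsum, DVS).

    DVS runs linearly 0→1 over TSUM1 and 1→2 over TSUM2, capped at 2.
    """
    if tsum1 <= 0 or tsum2 <= 0:
        raise ParameterError("TSUM1 and TSUM2 must be positive")
    if tsum_accum < 0:
        raise ParameterError("accumulated thermal time must be non-negative")
    tsum = tsum_accum + increment
    if tsum <= tsum1:
        dvs = tsum / tsum1
    else:
        dvs = 1.0 + (tsum - tsum1) / tsum2
    return tsum, min(dvs, 2.0)


def reference_et0(radiation: float, tmean: float, coef: float = 0.65) -> float:
    """Radiation-driven reference evapotranspiration (mm·d⁻¹).

    A Makkink-style form: et0 = coef × (Rs/λ) × f(T) with λ = 2.45 MJ·kg⁻¹
    and f a mild linear temperature factor standing in for Δ/(Δ+γ).
    """
    f = min(1.0, max(0.05, 0.45 + 0.012 * tmean))
    return coef * (radiation / 2.45) * f


def soil_water_step(
    sm: float,
    precip: float,
    et0: float,
    lai: float,
    soil: SoilParams,
    policy: IrrigationPolicy,
    k_ext: float = 0.60,
) -> tuple[float, float, float]:
    """One day of the soil water bucket.

    Returns ``(sm_new, irrigation_depth_cm, stress)``.  Irrigation triggers
    iff the policy is enabled and start-of-day moisture is strictly below
    SMc; the applied depth V cm raises moisture by V/root_depth.  Stress is
    the transpiration reduction factor in [0, 1], zero at the wilting point
    and one above the critical moisture level.
    """
    irrigation = 0.0
    if policy.enabled and sm < policy.smc:
        sm += policy.v / soil.root_depth
        irrigation = policy.v
    sm += precip / (10.0 * soil.root_depth)  # mm over root_depth cm of soil

    crit = soil.sm_crit
    stress = (sm - soil.sm_wilt) / (crit - soil.sm_wilt)
    stress = min(1.0, max(0.0, stress))

    cover = 1.0 - math.exp(-k_ext * lai)
    aet = et0 * min(1.0, cover) * stress  # mm
    sm -= aet / (10.0 * soil.root_depth)

    sm = min(sm, soil.sm_sat)  # drainage of any excess
    sm = max(sm, 0.5 * soil.sm_wilt)  # residual moisture floor
    return sm, irrigation, stress


def daily_growth(
    lai: float,
    organ_masses: tuple[float, float, float, float],
    radiation: float,
    tmean: float,
    dvs: float,
    dtsum: float,
    crop: CropParams,
    stress: float,
) -> tuple[float, tuple[float, float, float, float], float]:
    """One day of biomass growth.

    ``organ_masses`` is (living leaf, stem, storage, root) in kg·ha⁻¹.
    Gross assimilation follows a Beer-law light-interception × light-use-
    efficiency form; maintenance respiration is a Q10 function of organ
    masses capped at gross assimilation so net growth is never negative.
    Returns ``(gross_assimilation, organ_increments, lai_increment)``.
    """
    leaf, stem, storage, root = organ_masses
    cover = 1.0 - math.exp(-crop.k_ext * lai)
    gross = crop.eps_lue * 0.5 * radiation * cover * stress

    rm = (
        crop.rm_leaf * leaf
        + crop.rm_stem * stem
        + crop.rm_storage * storage
        + crop.rm_root * root
    ) * crop.q10 ** ((tmean - 25.0) / 10.0)
    net = max(0.0, gross - min(rm, gross))

    f_leaf = float(np.interp(dvs, crop.part_dvs, crop.part_leaf))
    f_stem = float(np.interp(dvs, crop.part_dvs, crop.part_stem))
    f_sto = float(np.interp(dvs, crop.part_dvs, crop.part_storage))
    f_root = float(np.interp(dvs, crop.part_dvs, crop.part_root))

    d_leaf = net * f_leaf
    increments = (d_leaf, net * f_stem, net * f_sto, net * f_root)

    if dvs < crop.dvs_juvenile:
        # juvenile phase: exponential LAI expansion, source-limited
        d_lai = min(lai * math.expm1(crop.rgrlai * dtsum), crop.sla * d_leaf)
    else:
        d_lai = crop.sla * d_leaf
    return gross, increments, d_lai


def senesce_leaves(
    cohorts: list[list[float]], tmean: float, span: float
) -> tuple[list[list[float]], float, float]:
    """Age leaf cohorts one day and retire those beyond their life span.

    Each cohort is a mutable ``[mass, age]`` pair; physiological age
    advances by max(0, tmean)/35 per day, so a leaf held at 35 °C lives
    exactly SPAN days.  Returns ``(surviving_cohorts, living_mass,
    newly_dead_mass)``.
    """
    rate = max(0.0, tmean) / LEAF_AGE_REF_TEMP
    surviving: list[list[float]] = []
    living = 0.0
    died = 0.0
    for cohort in cohorts:
        cohort[1] += rate
        if cohort[1] >= span:
            died += cohort[0]
        else:
            living += cohort[0]
            surviving.append(cohort)
    return surviving, living, died


# ---------------------------------------------------------------------------
# weather handling
# ---------------------------------------------------------------------------


def load_weather(path) -> pd.DataFrame:
    """Read a daily weather CSV (date, radiation, tmin, tmax, vap, wind, precip)."""
    df = pd.read_csv(path, parse_dates=["date"])
    return validate_weather(df)


def validate_weather(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise WeatherError(f"weather table missing columns: {missing}")
    df = df.sort_values("date").reset_index(drop=True)
    vals = df[["radiation", "tmin", "tmax", "precip"]].to_numpy(float)
    if not np.all(np.isfinite(vals)):
        raise WeatherError("non-finite weather values")
    if np.any(df["tmin"].to_numpy() > df["tmax"].to_numpy()):
        raise WeatherError("tmin exceeds tmax")
    if np.any(df["radiation"].to_numpy() < 0) or np.any(df["precip"].to_numpy() < 0):
        raise WeatherError("negative radiation or precipitation")
    return df


def load_params(path) -> tuple[CropParams, SoilParams, IrrigationPolicy]:
    """Read crop/soil/irrigation parameters from a YAML config.

    The file holds one section per parameter block (``crop``, ``soil``,
    ``irrigation``); every key is optional and overrides the documented
    default.  Unknown keys raise, to catch typos early.
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    crop = CropParams(**{k: v for k, v in (cfg.get("crop") or {}).items()})
    soil = SoilParams(**{k: v for k, v in (cfg.get("soil") or {}).items()})
    policy = IrrigationPolicy(**{k: v for k, v in (cfg.get("irrigation") or {}).items()})
    crop.validate()
    soil.validate()
    policy.validate(soil)
    return crop, soil, policy


class PreparedWeather:
    """Weather table pre-converted to numpy arrays for fast repeated runs.

    Optimizers re-run the season simulator hundreds of times on the same
    weather; this caches the date index and the per-day derived series that
    do not depend on crop parameters.
    """

    def __init__(self, df: pd.DataFrame):
        df = validate_weather(df)
        self.dates = df["date"].dt.normalize().to_numpy(dtype="datetime64[D]")
        if self.dates.size and np.any(np.diff(self.dates) != np.timedelta64(1, "D")):
            raise WeatherError("weather dates must be consecutive daily values")
        self.radiation = df["radiation"].to_numpy(float)
        self.tmin = df["tmin"].to_numpy(float)
        self.tmax = df["tmax"].to_numpy(float)
        self.precip = df["precip"].to_numpy(float)
        self.tmean = 0.5 * (self.tmin + self.tmax)
        self.et0 = 0.65 * (self.radiation / 2.45) * np.clip(
            0.45 + 0.012 * self.tmean, 0.05, 1.0
        )
        self.age_rate = np.maximum(0.0, self.tmean) / LEAF_AGE_REF_TEMP

    def index_of(self, day: date) -> int:
        d = np.datetime64(day, "D")
        idx = int(np.searchsorted(self.dates, d))
        if idx >= self.dates.size or self.dates[idx] != d:
            raise WeatherError(f"date {day} not covered by the weather series")
        return idx


# ---------------------------------------------------------------------------
# season run
# ---------------------------------------------------------------------------


@dataclass
class SeasonSeries:
    """Daily trajectory of one simulated season."""

    dates: np.ndarray  # datetime64[D], one per simulated day
    dvs: np.ndarray
    tsum: np.ndarray
    lai: np.ndarray
    agb: np.ndarray  # kg·ha⁻¹, living + dead aboveground organs
    twso: np.ndarray  # kg·ha⁻¹, storage organs
    sm: np.ndarray  # volumetric soil moisture
    irrigation: list = field(default_factory=list)  # (date, depth cm) events
    anthesis_date: date | None = None
    maturity_date: date | None = None
    truncated: bool = False

    @property
    def n_days(self) -> int:
        return int(self.dates.size)

    @property
    def max_lai(self) -> float:
        return float(self.lai.max())

    @property
    def final_agb(self) -> float:
        return float(self.agb[-1])

    @property
    def final_twso(self) -> float:
        return float(self.twso[-1])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": self.dates,
                "dvs": self.dvs,
                "tsum": self.tsum,
                "lai": self.lai,
                "agb": self.agb,
                "twso": self.twso,
                "sm": self.sm,
            }
        )

    def lai_on(self, days: np.ndarray) -> np.ndarray:
        """Simulated LAI sampled on arbitrary dates; 0 outside the season."""
        days = np.asarray(days, dtype="datetime64[D]")
        out = np.zeros(days.size)
        inside = (days >= self.dates[0]) & (days <= self.dates[-1])
        idx = (days[inside] - self.dates[0]).astype(int)
        out[inside] = self.lai[idx]
        return out


def run_season(
    weather: pd.DataFrame | PreparedWeather,
    crop: CropParams,
    soil: SoilParams,
    policy: IrrigationPolicy,
    emergence_date: date,
    max_days: int = 330,
    initial_sm: float | None = None,
) -> SeasonSeries:
    """Simulate one winter-wheat season from emergence to maturity.

    Daily order of operations: phenology → soil water → growth →
    senescence.  The run stops on the first day DVS reaches 2 (maturity) or
    when the weather series is exhausted (flagged ``truncated``).
    """
    crop.validate()
    soil.validate()
    policy.validate(soil)
    pw = weather if isinstance(weather, PreparedWeather) else PreparedWeather(weather)
    start = pw.index_of(emergence_date)
    n = min(max_days, pw.dates.size - start)
    if n < 1:
        raise WeatherError("no weather available at the emergence date")
    sl = slice(start, start + n)
    rad = pw.radiation[sl]
    tmean = pw.tmean[sl]
    precip = pw.precip[sl]
    et0 = pw.et0[sl]
    dates = pw.dates[sl]

    dtsum = np.maximum(0.0, tmean - crop.tbase_pheno)
    tsum = np.cumsum(dtsum)
    dvs = np.where(
        tsum <= crop.tsum1,
        tsum / crop.tsum1,
        1.0 + (tsum - crop.tsum1) / crop.tsum2,
    )
    dvs = np.minimum(dvs, 2.0)
    page = np.cumsum(pw.age_rate[sl])  # cumulative physiological leaf age

    f_leaf = np.interp(dvs, crop.part_dvs, crop.part_leaf)
    f_stem = np.interp(dvs, crop.part_dvs, crop.part_stem)
    f_sto = np.interp(dvs, crop.part_dvs, crop.part_storage)

    # initial state: TDWI split by the DVS=0 partition fractions
    leaf = crop.tdwi * crop.part_leaf[0]
    stem = crop.tdwi * crop.part_stem[0]
    storage = crop.tdwi * crop.part_storage[0]
    root = crop.tdwi * crop.part_root[0]
    dead_leaf = 0.0
    lai = crop.sla * leaf
    sm = soil.sm_fc if initial_sm is None else initial_sm

    # leaf cohorts: parallel lists (birth cumulative age, mass, LAI share)
    coh_page: list[float] = [0.0]
    coh_mass: list[float] = [leaf]
    coh_lai: list[float] = [lai]
    oldest = 0

    out_lai = np.empty(n)
    out_agb = np.empty(n)
    out_twso = np.empty(n)
    out_sm = np.empty(n)
    events: list[tuple] = []

    k_ext = crop.k_ext
    eps_half = crop.eps_lue * 0.5
    juv = crop.dvs_juvenile
    sla = crop.sla
    rgrlai = crop.rgrlai
    span = crop.span
    smc = policy.smc
    dsm_irr = policy.v / soil.root_depth
    irrigate = policy.enabled and policy.v > 0
    wilt, crit, sat = soil.sm_wilt, soil.sm_crit, soil.sm_sat
    inv_store = 1.0 / (10.0 * soil.root_depth)
    sm_floor = 0.5 * wilt
    q10 = crop.q10

    last = n - 1
    for i in range(n):
        # --- soil water ---
        if irrigate and sm < smc:
            sm += dsm_irr
            events.append((dates[i], policy.v))
        sm += precip[i] * inv_store
        stress = (sm - wilt) / (crit - wilt)
        stress = 1.0 if stress > 1.0 else (0.0 if stress < 0.0 else stress)
        cover = 1.0 - math.exp(-k_ext * lai)
        sm -= et0[i] * (cover if cover < 1.0 else 1.0) * stress * inv_store
        if sm > sat:
            sm = sat
        elif sm < sm_floor:
            sm = sm_floor

        if dvs[i] < 2.0:
            # --- growth ---
            gross = eps_half * rad[i] * cover * stress
            rm = (
                crop.rm_leaf * leaf
                + crop.rm_stem * stem
                + crop.rm_storage * storage
                + crop.rm_root * root
            ) * q10 ** ((tmean[i] - 25.0) / 10.0)
            net = gross - rm
            if net < 0.0:
                net = 0.0
            d_leaf = net * f_leaf[i]
            stem += net * f_stem[i]
            storage += net * f_sto[i]
            root += net * (1.0 - f_leaf[i] - f_stem[i] - f_sto[i])
            if dvs[i] < juv:
                d_lai = lai * math.expm1(rgrlai * dtsum[i])
                lim = sla * d_leaf
                if d_lai > lim:
                    d_lai = lim
            else:
                d_lai = sla * d_leaf
            if d_leaf > 0.0:
                leaf += d_leaf
                coh_page.append(page[i])
                coh_mass.append(d_leaf)
                coh_lai.append(d_lai)
                lai += d_lai

            # --- senescence (leaf age) ---
            cutoff = page[i] - span
            while oldest < len(coh_page) and coh_page[oldest] <= cutoff:
                leaf -= coh_mass[oldest]
                dead_leaf += coh_mass[oldest]
                lai -= coh_lai[oldest]
                oldest += 1
            # --- self-shading mortality above the critical LAI ---
            excess = lai - crop.lai_crit
            if excess > 0.0:
                target = excess * crop.shade_death_rate
                while target > 0.0 and oldest < len(coh_page):
                    if coh_lai[oldest] <= target:
                        target -= coh_lai[oldest]
                        lai -= coh_lai[oldest]
                        leaf -= coh_mass[oldest]
                        dead_leaf += coh_mass[oldest]
                        oldest += 1
                    else:
                        frac = target / coh_lai[oldest]
                        lai -= target
                        leaf -= coh_mass[oldest] * frac
                        dead_leaf += coh_mass[oldest] * frac
                        coh_lai[oldest] *= 1.0 - frac
                        coh_mass[oldest] *= 1.0 - frac
                        target = 0.0
            if lai < 0.0:
                lai = 0.0
            if leaf < 0.0:
                leaf = 0.0

        out_lai[i] = lai
        out_agb[i] = leaf + dead_leaf + stem + storage
        out_twso[i] = storage
        out_sm[i] = sm
        if dvs[i] >= 2.0:
            last = i
            break

    n_run = last + 1
    series = SeasonSeries(
        dates=dates[:n_run],
        dvs=dvs[:n_run],
        tsum=tsum[:n_run],
        lai=out_lai[:n_run],
        agb=out_agb[:n_run],
        twso=out_twso[:n_run],
        sm=out_sm[:n_run],
        irrigation=events,
        truncated=bool(dvs[n_run - 1] < 2.0),
    )
    i_anth = np.argmax(series.dvs >= 1.0)
    if series.dvs[i_anth] >= 1.0:
        series.anthesis_date = dates[i_anth].astype(date)
    if not series.truncated:
        series.maturity_date = dates[last].astype(date)
    return series


def crossing_day(cum_tsum: np.ndarray, threshold: float) -> float:
    """Fractional day offset (1-based) at which cumulative thermal time
    crosses a threshold, by linear interpolation within the crossing day."""
    if threshold > cum_tsum[-1]:
        return float("inf")
    return float(np.interp(threshold, cum_tsum, np.arange(1.0, cum_tsum.size + 1)))
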