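"""Per-pixel variational assimilation of 8-day satellite LAI.

Satellite LAI for winter wheat is known to run low relative to the actual
canopy, so absolute values are not trusted: the cost function compares the
*shape* of the observed and simulated LAI trajectories after min-max
normalization of each side,

    J = Σ_t ( (LAIobs_t − LAIobs_min)/(LAIobs_max − LAIobs_min)
            − (LAIsim_t − LAIsim_min)/(LAIsim_max − LAIsim_min) )²

and the simulator is re-initialized per pixel in the three parameters that
control the timing and persistence of the canopy: the emergence day
(IDEM, as an offset from the zonal crop calendar), the leaf life span
SPAN, and the emergence→anthesis thermal time TSUM1.  The optimum is found
by a deterministic hybrid search: a coarse integer scan over the emergence
offset (the emergence day is inherently integer-valued, which makes the
cost piecewise constant along that axis), alternating with a bounded
Nelder-Mead simplex over (SPAN, TSUM1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from wheatdas._optim import nelder_mead
from wheatdas.crop_model import (
    CropParams,
    IrrigationPolicy,
    PreparedWeather,
    SeasonSeries,
    SoilParams,
    run_season,
)

__all__ = [
    "AssimilationConfig",
    "DegenerateSeriesError",
    "LAIObservationSeries",
    "PixelInputs",
    "PixelResult",
    "assimilate_grid",
    "assimilate_pixel",
    "lai_cost",
    "minmax_normalize",
]


class DegenerateSeriesError(ValueError):
    """A series has zero amplitude and cannot be min-max normalized."""


@dataclass
class LAIObservationSeries:
    """Dated LAI observations at a nominal 8-day cadence within one season."""

    dates: np.ndarray  # datetime64[D]
    values: np.ndarray

    def __post_init__(self):
        self.dates = np.asarray(self.dates, dtype="datetime64[D]")
        self.values = np.asarray(self.values, float)
        if self.dates.size != self.values.size:
            raise ValueError("dates and values must have equal length")
        if self.dates.size < 3:
            raise ValueError("at least three LAI observations required")
        if np.any(np.diff(self.dates) <= np.timedelta64(0, "D")):
            raise ValueError("observation dates must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("LAI observations must be non-negative")

    @property
    def amplitude(self) -> float:
        return float(self.values.max() - self.values.min())

    @property
    def n(self) -> int:
        return int(self.dates.size)


@dataclass
class AssimilationConfig:
    """Search bounds, tolerances and degeneracy threshold for one pixel fit."""

    idem_half_range: int = 10  # days around the zonal emergence date
    span_bounds: tuple[float, float] = (15.0, 45.0)
    tsum1_rel_range: float = 0.15  # ±fraction around the zonal TSUM1
    amplitude_threshold: float = 0.2  # minimum LAI amplitude to attempt a fit
    maxfev: int = 150  # per simplex stage
    xtol: float = 1e-3
    scan_step: int = 2  # coarse emergence-offset scan step, days
    refine_rounds: int = 2


@dataclass
class PixelResult:
    idem_offset: float
    span: float
    tsum1: float
    cost: float
    initial_cost: float
    series: SeasonSeries
    status: str  # converged | skipped-degenerate | failed
    n_evaluations: int = 0


def minmax_normalize(values) -> np.ndarray:
    """Scale a series to [0, 1] by its own min and max."""
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("cannot normalize an empty series")
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise DegenerateSeriesError("series has zero amplitude")
    return (v - lo) / (hi - lo)


def lai_cost(obs_values, sim_values) -> float:
    """Normalized least-squares cost J between paired LAI series.

    Both series are min-max normalized over the paired values only, so J
    is invariant under positive affine transforms of either side (which is
    what makes the low-biased satellite product usable).
    """
    a = minmax_normalize(obs_values)
    b = minmax_normalize(sim_values)
    if a.size != b.size:
        raise ValueError("paired series must have equal length")
    return float(np.sum((a - b) ** 2))


def _cost_for(
    obs: LAIObservationSeries,
    weather: PreparedWeather,
    crop: CropParams,
    soil: SoilParams,
    policy: IrrigationPolicy,
    emergence: date,
    max_days: int,
) -> tuple[float, SeasonSeries | None]:
    try:
        series = run_season(weather, crop, soil, policy, emergence, max_days=max_days)
        sim = series.lai_on(obs.dates)
        return lai_cost(obs.values, sim), series
    except Exception:
        return np.inf, None


def assimilate_pixel(
    obs: LAIObservationSeries,
    crop: CropParams,
    soil: SoilParams,
    policy: IrrigationPolicy,
    weather: PreparedWeather | pd.DataFrame,
    emergence_date: date,
    config: AssimilationConfig | None = None,
    max_days: int = 330,
) -> PixelResult:
    """Fit (IDEM, SPAN, TSUM1) to one pixel's LAI series.

    The search starts at the zonal values and never returns a solution
    worse than the start (final J ≤ initial J).  Observation series whose
    amplitude is below the configured threshold are not fitted: the zonal
    (non-assimilated) run is returned with status ``skipped-degenerate``.
    """
    config = config or AssimilationConfig()
    pw = weather if isinstance(weather, PreparedWeather) else PreparedWeather(weather)

    def run_at(offset: int, span: float, tsum1: float):
        em = emergence_date + timedelta(days=int(round(offset)))
        return _cost_for(
            obs, pw, crop.evolve(span=span, tsum1=tsum1), soil, policy, em, max_days
        )

    if obs.amplitude < config.amplitude_threshold:
        try:
            series0 = run_season(pw, crop, soil, policy, emergence_date, max_days=max_days)
        except Exception:
            return PixelResult(0, crop.span, crop.tsum1, np.inf, np.inf, None, "failed")
        return PixelResult(
            0, crop.span, crop.tsum1, np.nan, np.nan, series0, "skipped-degenerate"
        )
    j0, series0 = run_at(0, crop.span, crop.tsum1)
    if series0 is None or not np.isfinite(j0):
        return PixelResult(0, crop.span, crop.tsum1, np.inf, np.inf, series0, "failed")

    nfev = 1
    best = (0, crop.span, crop.tsum1, j0)
    half = config.idem_half_range
    t1_lo = crop.tsum1 * (1.0 - config.tsum1_rel_range)
    t1_hi = crop.tsum1 * (1.0 + config.tsum1_rel_range)
    span_lo, span_hi = config.span_bounds
    span0 = min(max(crop.span, span_lo), span_hi)

    offset, span, tsum1 = 0, span0, crop.tsum1
    for round_i in range(config.refine_rounds):
        # coarse integer scan over the emergence offset
        step = config.scan_step if round_i == 0 else 1
        lo = -half if round_i == 0 else max(-half, offset - 2)
        hi = half if round_i == 0 else min(half, offset + 2)
        for cand in range(lo, hi + 1, step):
            j, _ = run_at(cand, span, tsum1)
            nfev += 1
            if j < best[3]:
                best = (cand, span, tsum1, j)
        offset = best[0]

        # simplex over (SPAN, TSUM1) at the scanned offset
        def neg(x, _offset=offset):
            nonlocal nfev
            nfev += 1
            j, _ = run_at(_offset, x[0], x[1])
            return j

        res = nelder_mead(
            neg,
            np.array([best[1], best[2]]),
            bounds=[(span_lo, span_hi), (t1_lo, t1_hi)],
            maxfev=config.maxfev,
            xtol=config.xtol,
        )
        if res.fun < best[3]:
            best = (offset, float(res.x[0]), float(res.x[1]), float(res.fun))
        span, tsum1 = best[1], best[2]

    if best[3] <= j0:
        j_final, series = run_at(best[0], best[1], best[2])
        return PixelResult(
            best[0], best[1], best[2], j_final, j0, series, "converged", nfev
        )
    return PixelResult(0, crop.span, crop.tsum1, j0, j0, series0, "converged", nfev)


@dataclass
class PixelInputs:
    """Everything needed to assimilate one masked pixel."""

    obs: LAIObservationSeries
    crop: CropParams
    soil: SoilParams
    policy: IrrigationPolicy
    weather: PreparedWeather
    emergence_date: date


def assimilate_grid(
    mask: np.ndarray,
    inputs: dict[tuple[int, int], PixelInputs],
    config: AssimilationConfig | None = None,
) -> tuple[dict[tuple[int, int], PixelResult], pd.DataFrame]:
    """Assimilate every masked pixel of a grid.

    Returns per-pixel results keyed by (row, col) and a diagnostics table
    with status and cost per pixel.  Pixels outside the mask emit nothing
    (no-data downstream); masked pixels without inputs are flagged failed.
    """
    results: dict[tuple[int, int], PixelResult] = {}
    rows = []
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if not mask[r, c]:
                continue
            px = inputs.get((r, c))
            if px is None:
                rows.append({"row": r, "col": c, "status": "failed", "cost": np.nan})
                continue
            res = assimilate_pixel(
                px.obs, px.crop, px.soil, px.policy, px.weather,
                px.emergence_date, config,
            )
            results[(r, c)] = res
            rows.append(
                {
                    "row": r,
                    "col": c,
                    "status": res.status,
                    "cost": res.cost,
                    "initial_cost": res.initial_cost,
                    "idem_offset": res.idem_offset,
                    "span": res.span,
                    "tsum1": res.tsum1,
                }
            )
    diagnostics = pd.DataFrame(rows)
    return results, diagnostics
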