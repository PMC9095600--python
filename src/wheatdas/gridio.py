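"""Product layout, raster I/O, validation metrics and utility conversions.

The published product is one georeferenced raster per harvest year with
exactly 270 daily bands covering the last 90 days of the previous
calendar year and the first 180 days of the harvest year (the winter-
wheat season window), in kg·ha⁻¹.  The window is defined by day counts,
so leap years shift the end calendar date (Jun 28 vs Jun 29) but never
the band count.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "NODATA",
    "SeasonWindow",
    "ValidationReport",
    "biomass_conversions",
    "county_error_map",
    "read_agb_stack",
    "season_window",
    "validation_metrics",
    "write_agb_stack",
]

N_BANDS = 270
DAYS_BEFORE = 90  # last N days of the previous year
DAYS_AFTER = 180  # first N days of the harvest year
NODATA = -9999.0

# GeoTIFF tags for a plain lon/lat grid
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922

#: empirical coefficient converting total biomass to net primary production
NPP_COEFFICIENT = 0.45


@dataclass
class SeasonWindow:
    """The 270-day daily window of one harvest year's product."""

    harvest_year: int
    start: date
    end: date
    dates: np.ndarray = field(repr=False)

    @property
    def n_bands(self) -> int:
        return int(self.dates.size)

    def band_of(self, day: date) -> int:
        """1-based band index of a calendar day within the window."""
        offset = (day - self.start).days
        if not (0 <= offset < self.n_bands):
            raise ValueError(f"{day} outside the {self.harvest_year} season window")
        return offset + 1


def season_window(harvest_year: int) -> SeasonWindow:
    """Build the harvest-year window: 90 + 180 consecutive days."""
    start = date(harvest_year - 1, 12, 31) - timedelta(days=DAYS_BEFORE - 1)
    end = date(harvest_year, 1, 1) + timedelta(days=DAYS_AFTER - 1)
    dates = np.arange(
        np.datetime64(start, "D"),
        np.datetime64(end, "D") + np.timedelta64(1, "D"),
    )
    assert dates.size == N_BANDS
    return SeasonWindow(harvest_year=harvest_year, start=start, end=end, dates=dates)


def write_agb_stack(
    stack: np.ndarray,
    window: SeasonWindow,
    path,
    cell_size: float = 0.01,
    origin: tuple[float, float] = (110.0, 40.0),
    nodata: float = NODATA,
) -> None:
    """Write one harvest year's daily AGB stack as a 270-band GeoTIFF.

    ``stack`` is (bands, rows, cols); ``origin`` is the (lon, lat) of the
    top-left corner.  Band→date mapping, units and the no-data sentinel
    are stored in the image description; pixel scale and tie-point tags
    carry the georeferencing.
    """
    stack = np.asarray(stack, np.float32)
    if stack.ndim != 3 or stack.shape[0] != N_BANDS:
        raise ValueError(f"stack must have exactly {N_BANDS} bands, got {stack.shape}")
    meta = {
        "harvest_year": window.harvest_year,
        "start": window.start.isoformat(),
        "end": window.end.isoformat(),
        "units": "kg/ha",
        "nodata": nodata,
        "cell_size": cell_size,
        "origin": list(origin),
    }
    scale = (cell_size, cell_size, 0.0)
    tiepoint = (0.0, 0.0, 0.0, origin[0], origin[1], 0.0)
    tifffile.imwrite(
        path,
        stack,
        photometric="minisblack",
        description=json.dumps(meta),
        extratags=[
            (_TAG_MODEL_PIXEL_SCALE, "d", 3, scale),
            (_TAG_MODEL_TIEPOINT, "d", 6, tiepoint),
        ],
    )


def read_agb_stack(path) -> tuple[np.ndarray, SeasonWindow, dict]:
    """Read a written product back: (stack, window, metadata)."""
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        page = tif.pages[0]
        desc = page.description
        tags = {t.code: t.value for t in page.tags.values()}
    if stack.ndim != 3 or stack.shape[0] != N_BANDS:
        raise ValueError(f"product must have exactly {N_BANDS} bands, got {stack.shape}")
    try:
        meta = json.loads(desc)
    except (TypeError, json.JSONDecodeError) as exc:
        raise ValueError("missing product metadata description") from exc
    if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
        raise ValueError("missing georeferencing tags")
    window = season_window(int(meta["harvest_year"]))
    if window.start.isoformat() != meta["start"]:
        raise ValueError("window metadata inconsistent with harvest year")
    return stack.astype(np.float32), window, meta


def validation_metrics(pred, obs) -> tuple[float, float, float]:
    """R² (1 − SS_res/SS_tot), RMSE and MAPE (%) of predictions vs observations."""
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    if pred.shape != obs.shape or pred.size < 2:
        raise ValueError("pred and obs must be equal-length vectors of size >= 2")
    if np.any(obs == 0):
        raise ValueError("MAPE undefined for zero observations")
    resid = pred - obs
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    rmse = math.sqrt(float(np.mean(resid**2)))
    mape = float(np.mean(np.abs(resid) / np.abs(obs))) * 100.0
    return r2, rmse, mape


@dataclass
class ValidationReport:
    r2: float
    rmse: float
    mape: float
    table: pd.DataFrame  # per-county simulated, observed, error, flagged
    flag_threshold: float = 2000.0

    @property
    def n_flagged(self) -> int:
        return int(self.table["flagged"].sum())


def county_error_map(
    max_agb_grid: np.ndarray,
    mask: np.ndarray,
    cell_county: np.ndarray,
    county_agb_obs: dict[int, float],
    flag_threshold: float = 2000.0,
) -> ValidationReport:
    """Compare per-county mean simulated maximum AGB with statistics-derived AGB.

    ``county_agb_obs`` maps county id to the statistics-derived AGB
    (fresh yield → dry matter → / harvest index), in kg·ha⁻¹.  Counties
    whose absolute error strictly exceeds ``flag_threshold`` are flagged;
    counties with no masked pixels are excluded.
    """
    rows = []
    for cid, obs_agb in sorted(county_agb_obs.items()):
        sel = (cell_county == cid) & mask
        if not np.any(sel):
            continue
        sim = float(np.mean(max_agb_grid[sel]))
        err = sim - obs_agb
        rows.append(
            {
                "county": cid,
                "simulated": sim,
                "observed": obs_agb,
                "error": err,
                "flagged": abs(err) > flag_threshold,
            }
        )
    if not rows:
        raise ValueError("no county with masked pixels to validate")
    table = pd.DataFrame(rows)
    if len(table) >= 2:
        r2, rmse, mape = validation_metrics(
            table["simulated"].to_numpy(), table["observed"].to_numpy()
        )
    else:
        resid = float(table["error"].iloc[0])
        r2, rmse, mape = (
            float("nan"),
            abs(resid),
            abs(resid) / float(table["observed"].iloc[0]) * 100.0,
        )
    return ValidationReport(
        r2=r2, rmse=rmse, mape=mape, table=table, flag_threshold=flag_threshold
    )


def biomass_conversions(agb: float, root_shoot_ratio: float) -> tuple[float, float]:
    """Total (above + below ground) biomass and NPP from aboveground biomass.

    total = AGB × (1 + root:shoot ratio); NPP = 0.45 × total.
    """
    if agb < 0 or root_shoot_ratio < 0:
        raise ValueError("inputs must be non-negative")
    total = agb * (1.0 + root_shoot_ratio)
    return total, total * NPP_COEFFICIENT
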