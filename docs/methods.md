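# Methods

This note documents the models, parameters, numerical choices and known
limitations of `wheatdas`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The reduced-form crop core

The simulator is deliberately a reduced form of the classic WOFOST
winter-wheat model. It keeps the state variables and the parameters that
the calibration and assimilation layers operate on — DVS, LAI, AGB, TWSO,
soil moisture; TSUM1, TSUM2, TDWI, SPAN, (SMc, V), the emergence day —
and replaces process detail that those layers never see:

- **Assimilation**: Beer-law interception × light-use efficiency,
  `A = ε · 0.5·R_s · (1 − e^(−k·LAI)) · stress`, instead of
  photosynthesis-light response curves integrated over the canopy.
  ε defaults to 30 kg·ha⁻¹ dry matter per MJ·m⁻² of intercepted PAR
  (3.0 g·MJ⁻¹, a standard winter-wheat value); PAR is taken as half of
  global shortwave radiation.
- **Respiration**: Q10 maintenance costs per organ
  (leaf 0.022, stem 0.012, storage 0.010, root 0.010 d⁻¹ at 25 °C,
  Q10 = 2), capped at gross assimilation so net growth is never negative
  — this is what makes the AGB trajectory non-decreasing, since dead
  organs stay in the aboveground pool.
- **Phenology**: thermal time above a 0 °C base using the daily mean
  (tmin+tmax)/2. DVS is piecewise linear: `tsum/TSUM1` to anthesis,
  `1 + (tsum−TSUM1)/TSUM2` to maturity. No vernalization or photoperiod:
  the season starts at the observed emergence date, which absorbs most of
  what those mechanisms would control at this scale.
- **Partitioning**: a piecewise-linear table of net-growth fractions vs.
  DVS (nodes at 0, 0.65, 0.95, 1.2, 2.0) sending everything to storage
  organs from DVS 1.2 onwards. Fractions sum to 1 at every node and are
  validated on construction.
- **Leaf dynamics**: leaves are tracked as daily cohorts whose
  physiological age advances by `max(0, T_mean)/35` per day, dying at age
  SPAN — so SPAN is exactly the life span at 35 °C. LAI growth is
  source-limited (`SLA ×` leaf growth) with an exponential cap
  (`RGRLAI` per °C·d) during the juvenile phase (DVS < 0.3). In addition,
  LAI above a critical value (6.0) decays toward it at 0.05 d⁻¹ of the
  excess, consuming the oldest cohorts first. This self-shading mortality
  is part of the core design: without it the interception feedback lets
  mild winters push the canopy to nonphysical peaks (LAI > 12) and makes
  the interannual harvest-index ratio unstable. Full WOFOST carries
  equivalent mortality terms.
- **Soil water**: a single bucket over the root zone (default 100 cm).
  Order per day: irrigation trigger (start-of-day SM < SMc adds
  V/root_depth), precipitation, transpiration reduction factor
  `stress = clamp((SM − SM_wilt)/(SM_crit − SM_wilt), 0, 1)` with
  SM_crit halfway between wilting point and field capacity, actual ET
  `= ET0 · min(1, cover) · stress`, drainage of any excess above
  saturation, and a residual floor at half the wilting point. Reference
  ET is a Makkink-style form `ET0 = 0.65 · (R_s/2.45) · f(T)` with
  `f(T) = clamp(0.45 + 0.012·T, 0.05, 1)` standing in for Δ/(Δ+γ); only
  the *relative* soil-moisture behaviour matters for the (SMc, V)
  optimization, so a documented, configurable constant is preferable to
  an unconstrained Penman-Monteith implementation.

Daily order of operations: phenology → soil water → growth → senescence.
The run stops on the first day DVS reaches 2, or flags `truncated` when
weather runs out. The simulator is deterministic: identical inputs give
bit-identical trajectories.

Default parameters (all overridable via `CropParams`/`load_params`):
TSUM1 1000 °C·d, TSUM2 800 °C·d, TDWI 80 kg·ha⁻¹, SPAN 30 d,
SLA 0.0019 ha·kg⁻¹, k 0.60. These were chosen once so that the default
season under the synthetic climate is a realistic irrigated winter-wheat
crop: peak LAI ≈ 6.3 (matching the station max-LAI distribution's mean of
6.5), AGB at maturity ≈ 17 t·ha⁻¹, harvest index ≈ 0.39.

## Zonal parameterization

Cells are assigned to the nearest station by Euclidean distance, ties
broken toward the lowest station id; this is the Thiessen-polygon
partition without any polygon geometry. Gravimetric soil-water constants
convert to volumetric by multiplying with bulk density (water density
1 g·cm⁻³); results ≥ 1 are rejected as inconsistent. Missing anthesis
observations are reconstructed as heading + 7 calendar days. TSUM1/TSUM2
are fit by minimizing the squared day errors of simulated vs. observed
anthesis and maturity; the simulated dates use fractional interpolation
of the cumulative thermal-time crossing, which makes the objective smooth
and lets a simplex search refine the closed-form single-year starting
values.

## Likelihood calibration

The objective is the sum of three multivariate Gaussian log-likelihood
blocks (annual maximum LAI, TWSO, AGB) over d jointly calibrated years
(3 by default; years missing a county statistic are dropped and d reduced).
Covariances are diagonal — years are treated as independent — with the
LAI SD 1.5 around a per-year mean of 6.5 (the station histogram), and the
yield/biomass SDs at 10% of each statistical value. The term is evaluated
by Cholesky factorization; non-positive-definite covariances raise.
County yields convert to dry matter at the standard 12.5% moisture and to
AGB through the provincial harvest index.

Quantile conventions: counties are ranked descending by mean yield,
groups split at positions `0.33·(n−1)` and `0.67·(n−1)`, and
representatives taken at positions `round(q·(n−1))` (half-up) for
q ∈ {0.17, 0.50, 0.83}. Zones with fewer than three counties fall back to
a single group represented by the median county, flagged.

All fits share one bounded Nelder-Mead wrapper operating on the unit box
spanned by the parameter bounds (relative tolerance 10⁻⁴, max 2000
evaluations), with an explicit initial simplex of 0.15 bound-widths so
the search moves meaningfully even from a zero coordinate (e.g. V = 0).
The crop-parameter step additionally uses a deterministic three-point
multi-start (the configured start and the same start scaled 0.9×/1.1×):
the likelihood surface has a TDWI × SPAN compensation ridge on which a
single simplex can park with near-optimal outputs but biased parameters.
No randomness is involved anywhere in the optimization.

The three-step strategy — crop parameters, then the six per-year
irrigation parameters (SMc, V), then crop parameters again with
irrigation fixed — starts each step from the incumbent solution and
falls back to it when a search cannot improve, so the objective sequence
is non-decreasing up to optimizer tolerance by construction.

**Identifiability.** The free crop-parameter set defaults to
{TDWI, SPAN, SLA, ε} with TSUM1/TSUM2 pre-fit from phenology; it is a
configuration list because the appropriate subset depends on the data
actually available. Two structural limits are worth knowing. First, the
irrigation pair (SMc, V) is identified from annual yields only through
the seasonal water total: schedules applying the same total water at
slightly different times produce identical yields, so per-event V is not
recoverable even from noise-free data (total applied water is, to a few
percent). Second, exact parameter recovery requires observation
consistency — the LAI target must be the max LAI the truth actually
attains and the harvest index the county's own per-year TWSO/AGB ratio;
with the climatological prior N(6.5, 1.5²) and a constant provincial HI,
the optimum is deliberately a compromise between the yield statistics and
the LAI climatology, not a parameter-recovery device.

## LAI assimilation

Satellite LAI for winter wheat is biased low relative to the actual
canopy, so the cost compares min-max-normalized trajectories; J is
invariant under any positive affine transform of either series, which is
what makes the biased product usable. The pairing rule samples simulated
LAI on the exact observation dates (0 outside the simulated season), and
normalization min/max are computed over the paired values only, per side.

The re-initialized triple is (IDEM, SPAN, TSUM1): emergence-day offset
within ±10 d of the zonal calendar, SPAN in [15, 45] d, TSUM1 within ±15%
of the zonal value (all configurable). Because the emergence day is
integer-valued the cost is piecewise constant along that axis, so the
optimizer is a deterministic hybrid: a coarse integer scan over the
offset, a bounded simplex over (SPAN, TSUM1), and one ±2-day refinement
round. The result never exceeds the starting cost (the zonal start is
returned if no improvement is found). Observation series with amplitude
below 0.2 LAI are skipped as degenerate and the zonal run returned.
Irrigation parameters stay fixed at their zonal values during the
per-pixel fit.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not any particular geography:

- **Weather**: sinusoidal annual temperature (mean 10 °C, amplitude
  14 °C, coldest mid-January) with Gaussian daily noise (SD 2 °C),
  radiation co-varying with day length, and a two-state precipitation
  occurrence chain with exponential wet-day amounts. The climate is
  chosen so that a 10 October emergence reaches anthesis in May and
  maturity in late June, inside the 270-day product window.
- **Region**: stations on a jittered lattice; counties chunk each
  Thiessen zone; a Bernoulli winter-wheat mask with configurable
  coverage.
- **Truth**: per-zone, per-yield-level crop parameters (ε ×1.15/1.0/0.85,
  TDWI ×1.1/1.0/0.9, SPAN ±3 d for high/medium/low) plus optional
  per-pixel perturbations of the emergence day (±6 d), SPAN (±5 d) and
  TSUM1 (±10%) — exactly the quantities the assimilation layer recovers.
- **Observations**: county fresh yield = county-mean dry TWSO / 0.875 ×
  (1 + noise, SD 10%); station max-LAI draws from N(6.5, 1.5²); pixel
  LAI = daily truth sampled every 8 days × 0.7 bias + additive noise
  (SD 0.1), lightly smoothed with a 3-point moving average standing in
  for the Savitzky-Golay-filtered satellite product.

All draws flow from one root seed through named substreams
(weather/region/pixels/observe), so every scenario regenerates
bit-identically. A `noise_free()` constructor switches off every noise
source for recovery experiments, and the generator exports the
truth-consistent observation targets those experiments need
(`group_truth_maxlai`, `county_hi_by_year`).

What passing tests do **not** show about real data: the synthetic weather
has no interannual regimes, fronts or heat waves; the satellite emulation
has no compositing artefacts, cloud gaps or mixed pixels; counties are
spatially compact and never straddle zones; and the truth is generated by
the same model family that is being fit, so structural model error — the
dominant uncertainty in real deployments — is absent by construction.

## Product layout and validation

Each harvest year's product is a single raster of exactly 270 daily
bands: the last 90 days of the previous calendar year plus the first 180
days of the harvest year, defined by day counts so leap years shift the
end date (28 vs 29 June) but never the band count. Rasters are written as
multiband GeoTIFFs (float32, no-data −9999, pixel-scale and tie-point
tags, band→date mapping and units in the image description). Validation
uses R² = 1 − SS_res/SS_tot (not squared correlation), RMSE, and MAPE;
the county error map flags counties whose mean simulated maximum AGB
differs from the statistics-derived AGB by strictly more than
2000 kg·ha⁻¹. Utility conversions: total biomass = AGB × (1 + root:shoot
ratio), NPP = 0.45 × total biomass.

## Problem sizes

Recovery experiments and the acceptance script use desk-scale problems
chosen to exercise every code path with stable statistics: a 6×6 single-
zone region with 9 counties and 3 years for calibration recovery, 5×5
grids across 20 seeds for the paired-improvement experiment, and 200
randomized single-season runs for the simulator invariant sweep. A single
season simulates in about a millisecond, one three-step zone calibration
in well under a minute, and one pixel assimilation in a fraction of a
second on one CPU.

## Known limitations

- The crop core is not WOFOST: absolute biomass levels depend on the
  light-use-efficiency and respiration defaults, and no claim is made
  that they transfer to any particular region without recalibration.
- No nutrient limitation, pests, lodging, or frost kill; water is the
  only stress.
- Counties are assigned to zones by centroid; counties spanning several
  zones are not split.
- The 3-year calibration windows are consecutive and non-overlapping.
- Sequential filters (EnKF, particle) and assimilation of variables other
  than LAI are out of scope.
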