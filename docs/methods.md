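# Methods

This document records the modelling assumptions, default parameters and
numerical choices behind `smokeval`. The package evaluates a gridded
wildfire-smoke PM2.5 forecast against monitor observations and observed smoke
plumes, and estimates associations between daily smoke exposure and
area-level health counts — all on a synthetic study whose generating
parameters are known, so every stage can be validated by recovery.

## 1. Synthetic study generator

### Geography

A square domain (default 600 km side) is tiled into `n_areas` (default 89)
rectangular health areas in a near-square row/column layout. Each area
receives a uniform number of census-unit points (default 3–474) at uniform
interior positions, each carrying a uniform population (default 400–700
persons). Monitors (default 36) are uniform over the domain. All coordinates
are planar kilometres; distances are Euclidean.

### Forecast field

Daily PM2.5 forecasts live on a 10 km grid. The marginal distribution is a
three-component mixture chosen to be strongly zero-inflated and right-skewed
with heavy episode concentrations:

- zeros with probability 0.60;
- "haze" halo cells ~ LogNormal(ln 0.03, 1.0);
- episode-core cells (3% of the domain in expectation) ~
  LogNormal(4.71, 0.60).

The pooled closed-form moments are mean ≈ 4.0 µg/m³ and SD ≈ 27.3 µg/m³.
Positive cells are spatially organised: each day the positive-cell count is
binomial, and positives grow as contiguous blobs (randomized edge-connected
accretion) around episode centres that advect across days with reflecting
boundaries; the innermost accreted cells form the heavy core. A configurable
number of days (default 2 of 35) is marked unavailable — an availability
artifact: health counts are always generated from the full field.

### Plumes

The forecast plume of a day is the union of all grid cells with value > 0, so
its area is exactly the cell area times the positive-cell count. Synthetic
"observed" plumes are the forecast plume translated by `plume_shift_km`
(default 230, random per-day direction) and buffered by `plume_dilation_km`
(default 30). With both set to zero the observed plume equals the forecast
plume and the daily FMS is exactly 1; the defaults give a mean daily FMS of
about 0.21, i.e. substantial but imperfect forecast/observation plume overlap.

### Monitors

The daily mean at a monitor is max(0, coupling × colocated forecast +
background + Gaussian noise) with defaults coupling 0.5, background 8 µg/m³,
noise SD 4 µg/m³. Hourly values scatter multiplicatively around the daily
mean with centred uniform jitter (±30%), so the 24-hour mean is exact.
Contamination for QC testing: isolated missing hours (p = 0.01/hour),
consecutive missing runs of 3–8 hours (p = 0.02/monitor-day), and filter
pressure drawn above the 60% threshold with p = 0.01/hour (61–95%) versus
10–55% otherwise. `agreement_coupling` is the single knob controlling
forecast-observation agreement; the global index of agreement rises
monotonically with it (validated over replicate seeds).

### Temperature

Per-monitor daily maximum temperature is a smooth sinusoid (base 25 °C,
amplitude 6 °C, period 70 days, random phase) plus Gaussian noise (SD 1.5 °C);
each area uses the monitor closest to its centroid.

### Health counts

For each outcome (defaults: "dispensations", true RR 1.08 per 30 µg/m³,
baseline 17.7–72.2 events/100k person-days, weekend multiplier 0.42, data in
85 of 89 areas; "physician_visits", RR 1.05, baseline 2.7–21.1/100k,
multiplier 0.32, 73 areas), area-day counts are Poisson with

log rate/person-day = per-area log baseline (log-uniform in the configured
range) − log 10⁵ + β·X_at + log(weekend multiplier)·1[weekend or holiday]
+ 0.01·(tmax − 25 °C) + mean-one lognormal overdispersion (SD 0.05),

where X_at is the lag 0–1 population-weighted forecast PM2.5 (the
truth-generating exposure) and β = ln(RR)/30. Per-area baseline heterogeneity
induces strong within-area correlation (fitted exchangeable α ≈ 0.8), which
is exactly what the GEE working correlation addresses.

## 2. Monitor quality control

Hourly PM2.5 is invalidated when filter pressure strictly exceeds 60%
(overloaded sampler). A daily mean is computed over the valid hours of the
24-hour window and declared missing with reason `total_missing` when ≥ 6
hours are missing in total, or `consecutive_missing` when ≥ 3 consecutive
hours are missing (total rule checked first; absent rows count as missing;
duplicate timestamps are an error).

## 3. Exposure assignment

Grid values are looked up with half-open cells [min, max) and value 0 outside
the grid (no smoke forecast beyond the domain). Monitor exposure uses the
nearest monitor with a non-missing QC'd daily value (ties broken by monitor
id). Area-day aggregation is the population-weighted mean over the area's
census points with pairwise missing exclusion. Plume flags are 1 when
strictly more than 50% of the area's population lies under the plume
(boundary points count as covered, keeping the flag monotone under plume
dilation). Lag 0–1 exposures average the same and previous day (binary: OR);
a missing previous day falls back to the same-day value, a missing same-day
value stays missing. Days with an unavailable forecast yield missing forecast
exposures and are dropped complete-case downstream.

## 4. Forecast verification

Monitor-day pairs (QC'd daily observation vs colocated forecast, available
days only) feed: Willmott's index of agreement, Pearson r, NRMSE (percent,
normalized by the observed range by default; mean or SD selectable),
fractional bias (bounded [−2, 2]), and Bland–Altman limits of agreement
(bias ± 2 SD of forecast−observed differences; zero-forecast pairs excluded).
Statistics are computed globally, per day across monitors ("spatial") and per
monitor across days ("temporal"); slices with fewer than 2 pairs are skipped.
The daily figure of merit in space is the area of the intersection over the
area of the union of the forecast-derived and observed plume sets (both
empty: undefined; exactly one empty: 0).

## 5. Health-association models

For each outcome and exposure (forecast PM2.5, truncated forecast PM2.5 at
300 µg/m³, nearest-monitor PM2.5, forecast-plume flag, observed-plume flag),
a marginal Poisson model with log-population offset is fitted by GEE with an
exchangeable working correlation over areas, adjusting for daily maximum
temperature (linear), day-of-week indicators (Monday reference), a holiday
indicator and study-week indicators (first week reference). Adjustment
indicators without variation in the data (e.g. no holiday in a short window)
are dropped. Truncation caps the daily exposure before lag-averaging.
Analyses are repeated within "very smoky" / "less smoky" area strata (areas
at or above vs below the rounded mean number of observed-plume coverage
days).

### GEE implementation

`PoissonGEE` solves Σᵢ Dᵢ'Vᵢ⁻¹(yᵢ − μᵢ) = 0 by Fisher scoring from the
independence (Poisson ML) start, exploiting the closed-form inverse of the
exchangeable correlation R(α) = (1−α)I + αJ so each update needs only
per-cluster column sums. The correlation α and dispersion φ are re-estimated
each iteration by their Pearson-residual moment estimators. Covariances:
model-based φ(ΣD'V⁻¹D)⁻¹ and the robust sandwich, optionally with the
Mancl–DeRouen small-sample residual correction. Point estimates, α and
robust standard errors agree with an independent reference implementation to
numerical precision (asserted in tests; the reference is used only as a test
oracle).

### Small-sample inference

Smoke exposure is spatially concentrated: in a typical default scenario a
handful of areas carry most of the exposure information, so although the
sandwich SE is approximately unbiased, the usual normal reference
undercovers. `PoissonGEE` therefore reports a per-coefficient Satterthwaite
effective df computed from the spread of per-cluster influence contributions
H⁻¹uᵢ — df = (Σaᵢ²)²/Σaᵢ⁴ — and rate-ratio confidence intervals use t
quantiles at that df (median effective df ≈ 6 of 85 areas for the forecast
exposure). Measured over 100 replicates of the default study, 95% CI
coverage is 0.92 (dispensations) and 0.98 (physician visits); with a normal
reference it would be 0.83/0.96.

## 6. Determinism and numerics

All randomness derives from a single seed via named independent substreams
(region, smoke, missing days, plume mismatch, monitors, temperature, health),
so e.g. skipping plume derivation does not perturb the other outputs.
Replicate studies draw 31-bit child seeds from a master seed. CSV artifacts
use fixed float formatting and timings are confined to `run.log`, making
pipeline reruns bit-identical (asserted in tests). Linear predictors are
clipped at |η| = 700 with step-halving to avoid overflow; exchangeable α is
clipped to its positive-definiteness range.

## 7. What the generator does and does not emulate

It emulates: zero-inflated heavy-tailed smoke fields with contiguous moving
episodes, forecast-observation mismatch at monitors and in plume position,
realistic QC contamination, strong between-area baseline heterogeneity,
weekend/holiday rate drops, and a temperature confounder. It does not
emulate: within-area day-to-day autocorrelation of counts beyond the shared
exposure (the overdispersion term is independent across days), reporting
delays, population mobility, or chemistry/meteorology of real dispersion
models; plume mismatch is a rigid shift plus dilation rather than a
shape-dependent error field. The haze component's inter-quartile range is
somewhat smaller than a typical real distribution with the same mean and SD.

## 8. Key defaults

| Parameter | Default | Meaning |
|---|---|---|
| `n_areas` / `n_days` / `n_monitors` | 89 / 35 / 36 | study size |
| `domain_km` / `grid_cell_km` | 600 / 10 | geometry |
| `forecast_zero_prob` | 0.60 | zero-inflation of the daily field |
| `episode_cell_prob` | 0.03 | expected episode-core fraction of domain |
| `plume_shift_km` / `plume_dilation_km` | 230 / 30 | plume mismatch (mean FMS ≈ 0.21) |
| `agreement_coupling` | 0.5 | forecast→monitor coupling |
| `obs_background_mean` / `obs_noise_sd` | 8 / 4 µg/m³ | monitor background/noise |
| truncation cap | 300 µg/m³ | forecast exposure truncation |
| coverage threshold | 0.5 | plume flag population fraction |
| increment | 30 µg/m³ | RR reporting increment |

All defaults are package choices for a realistic mid-size provincial smoke
season and can be overridden via `ScenarioConfig` or a YAML/JSON config file.
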