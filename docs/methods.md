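# Methods

## Scope and design

The package estimates rice production potential bottom-up: simulate
potential yield per weather station and cultivar, upscale by
harvested-area weights through climate zones, account for exploitable
yield gaps, and project production scenarios.  Every stage is exercised
end-to-end on synthetic inputs with known ground truth; the desk-scale
accounting (upscaling, gaps, scenarios) additionally runs on published
national values, which are carried in the scenario configuration.

## Crop model

A deliberately simple daily-step radiation-use-efficiency (RUE) model
in the tradition of process-based rice simulators.  It reproduces the
canonical chain phenology → leaf area → assimilation → partitioning →
yield but intentionally replaces canopy-layer photosynthesis with
Beer's-law interception and a single RUE: it is ORYZA-inspired, not
ORYZA, and no fidelity to any specific simulator's internals is
claimed.

**Phenology.** Development stage dvs runs 0 → 1 → 2 (emergence,
flowering, maturity) through four phases — juvenile (0–0.40),
photoperiod-sensitive (0.40–0.65), panicle development (0.65–1.0),
reproductive (1.0–2.0) — each advanced by its development rate
(`dvrj`, `dvri`, `dvrp`, `dvrr`, units (°Cd)⁻¹) times daily thermal
time.  Thermal time is the daily mean of Tmax/Tmin clipped to
[tbase, thigh] minus tbase, with no hourly interpolation (a documented
simplification).  Photoperiod response is disabled — `dvri` acts as a
plain thermal rate — reflecting the near-insensitivity of modern
high-yield cultivars.  Phase rates switch at the exact sub-daily
boundary crossing, which makes phenology calibration an exactly
invertible problem.  Sowing-to-emergence costs a fixed 75 °Cd
(configurable).  Seasons that fail to mature within 250 days raise a
"season too short" error that signals cool-climate infeasibility.

**Growth.** Green LAI = SLA × leaf mass × a green fraction that
declines linearly after flowering (to 0.30 at maturity).  Interception
is 1 − exp(−k·LAI) with k = 0.5.  Gross growth = RUE × intercepted
shortwave × a piecewise-linear temperature factor (0 at tbase = 8 °C,
1 at topt = 30 °C, 0 at thigh = 42 °C).  Maintenance respiration is
0.004 d⁻¹ of standing biomass with Q10 = 2 referenced to 25 °C.  Net
growth is partitioned to leaf/stem/panicle by a stage-indexed step
table; 20 % of stem mass at flowering is treated as remobilizable
reserves credited to grain at 75 % efficiency.  Yield is panicle mass
plus mobilized reserves, capped at a maximum harvest index of 0.55.
Mass balance closes by construction: the daily change in total biomass
equals net assimilation exactly (leaf senescence reduces green area,
not biomass), which the tests verify to 1e-9 t/ha.

**Defaults.** Development rates of a ~120-day indica cultivar
(0.000773/0.000749/0.000564/0.001904), RUE 2.2 g DM per MJ intercepted,
SLA 0.014 m² g⁻¹.  These were set so that a subtropical station
produces per-season potential yields near 10 t/ha, above-ground biomass
~22–24 t/ha, peak LAI ~7, a ~115–125-day season and a temporal CV near
8 % — the magnitudes reported for well-watered experimental rice.  All
are ordinary cultivar parameters, configurable per simulation.

**Calibration.** `calibrate_phenology` inverts the phenology model
from observed phase-boundary dates: for each phase in fixed order
(dvrj, dvri, dvrp, dvrr) a bounded one-dimensional search minimizes
the squared error between predicted and observed boundary dates, each
phase chained from the previous fitted boundary.  The observation
record includes all four phase boundaries (end of juvenile, panicle
initiation, flowering, maturity, as fractional days): with only the
classically reported emergence/PI/flowering/maturity dates, the
juvenile and photoperiod rates would be structurally confounded.  At
zero noise recovery is exact.  Under observation noise the short
photoperiod-sensitive phase (~18 days in warm climates) sets a noise
floor: with 2-day date noise and three site-years the best achievable
relative error on `dvri` has a standard deviation near 7 %, so
recovery within 5 % cannot be guaranteed for that rate — a property of
the experiment size, not of the estimator.  `calibrate_partitioning`
recovers the partition step table from organ increments between
samples (assigned to table intervals by midpoint dvs, pooled, clipped
to [0,1] and renormalized) and SLA by a through-origin regression of
vegetative LAI on leaf mass; with samples taken at the table's dvs
edges recovery is exact.

**Fit metrics.** r² is the squared Pearson correlation of simulated
versus observed; RMSE and RMSE as percent of the observed mean are the
standard agreement measures.  Zero-variance inputs leave r² undefined
(NaN with a warning) while RMSE is still returned.

## Weather generator and QC

Temperature is a site-preset annual sinusoid (peak near 20 July) plus
AR(1) noise (ρ = 0.75, sd 1.6 °C) and a yearly anomaly (sd 0.6 °C);
radiation is the extraterrestrial envelope (standard solar-geometry
closed form) times beta-distributed transmissivity capped at 0.75 with
a yearly anomaly (sd 5.5 %); rainfall is a two-state Markov occurrence
chain with gamma amounts; wind and humidity are lognormal/normal
noise.  The yearly anomalies are what give simulated potential yield a
realistic interannual CV (~5–11 % depending on seed).  Three presets
(cool-temperate, warm-temperate, subtropical) span the rice-growing
climates.  All generators are pure functions of spec + seed.

The generator emulates marginal distributions and seasonality, not
weather-system dynamics: no spatial correlation between sites, no
monsoon onset timing, no typhoons or cold surges.  Passing tests
therefore demonstrate correctness of the analysis chain, not skill of
the crop model against real Chinese weather.

Quality control flags days with Tmax < Tmin, radiation above the
clear-sky envelope (0.75 × extraterrestrial), negative rain, and
missing values; flagged values are masked, isolated single-day gaps
are imputed from neighbours, and a series with more than 10 % flagged
days is rejected.  Valid data are never altered.

## Zonation and upscaling

Climate zones bin three annual summaries: growing degree days (base
10 °C), aridity index (rain over Hargreaves reference
evapotranspiration — chosen because it needs only temperature and
radiation, and the PET method behind published zonation tables is not
fixed; configurable), and temperature seasonality (sd of monthly
means).  Default bin edges ship in `zonation.DEFAULT_BIN_EDGES`; zone
counts are a property of the grid and edges, so the test fixtures
construct a toy country with a known zone count rather than claiming
any real map.  Buffers use great-circle distance (R = 6371 km) on cell
centers with a closed 100-km boundary, clipped to the station's zone.
Station selection is greedy by remaining (unclaimed) rice area, so
selected buffers partition the covered area and area weights never
double-count; ties break to the lexicographically first station id.

County yields are reconciled to provincial statistics by a single
multiplicative factor per province, skipped when the area-weighted
county mean is within ±5 % of the official value; the adjustment is
idempotent.  Current farm yield is the unweighted mean across window
years (default 2010–2014) of area-weighted county means.  Double-rice
potential per season is the arithmetic mean of the early and late
crops (county statistics do not separate them); annual potential is
their sum, and all double-rice yields are per harvested area, so
production totals use season-summed area with no extra factor of two.

## Scenario engine

Per-system 2030 yield = anchor + rate × 15 years, optionally capped at
c × Yp (c = 0.75 or 0.80).  The stagnation scenario anchors at current
yield with rate 0; trend scenarios anchor at the fitted national trend
evaluated in the base year 2015, so the uncapped 2030 yield equals the
trend line at 2030; the accelerated scenario raises the double-rice
rate to 0.05 t/ha/yr from the same anchor.  Production = yield ×
fixed harvested area; rounding (yields 0.1 t/ha, production 0.1 MMT,
totals and balances whole MMT) is applied only at report time.

The shipped configuration carries the published national inputs with
two back-derivations, both documented in the YAML: harvested areas of
18.2 / 12.0 Mha reproduce current production (135.4 / 71.0 MMT) at the
unrounded current yields, and the single-rice potential yield is
carried at 10.34 t/ha (one-decimal reported value 10.3) because the
ceiling arithmetic is sensitive in the second decimal — with it, both
the 80 % and 75 % ceilings reproduce the published per-system scenario
yields and production.  The upscaling examples use areas back-derived
as production ÷ reported yields (18.30 / 12.03 Mha).  National
percentages are computed from report-precision yields (6.8/9.8 → 69 %),
matching how a published table is read; the unrounded ratio is half a
point higher.

The exploitable gap is max(0, c·Yp − Ya) per season.  At the national
scale this gives 1.3 t/ha for double-rice and 0.84 t/ha for
single-rice at the 80 % ceiling; the commonly quoted single-rice figure
of 0.9 t/ha is the difference of the scenario-table yields at
reporting precision (8.3 − 7.4), and both routes are reported.  The
production totals (+31 MMT at 80 %, +16 MMT at 75 %) follow from the
exact arithmetic.

## Trend fitting

Linear trends are ordinary least squares.  The two-segment piecewise
fit parameterizes the curve by its endpoint values (a at the first
year, b at the breakpoint, c at the last year) so continuity holds by
construction; the integer breakpoint is chosen by exhaustive SSE
search strictly inside (t₁+1, t₂−1), ties to the earliest year, and
candidates leaving fewer than two points per segment are skipped.
Because the piecewise family nests the line, its SSE never exceeds the
linear SSE.

## Top-down comparison

Any gridded potential-yield layer joins the harvested-area grid by
nearest cell center; zero-area cells are retained but weightless.  The
percent difference uses the bottom-up layer as denominator
(configurable), the relative gap is bottom-up Ya over top-down Yp × 100
(top-down farm-yield layers are typically outdated), and units whose
top-down 80 %-exploitable production falls below current production
are flagged.  National weighted means are invariant to partition
refinement, which the tests assert.

## Numerical conventions and limitations

* Determinism: every stochastic function takes an explicit seed; no
  global RNG state.
* Degenerate inputs raise (`ValueError`) rather than warn wherever a
  result would be meaningless: empty extents, zero areas, zero PET,
  unreachable phenological stages, seasons that cannot mature.
* Farm yield above potential (possible with noisy synthetic data)
  warns but does not raise; percentages then exceed 100.
* The simulator omits nitrogen, water limitation, pests, cold-sterility
  and CO₂ response — it targets potential yield only, and real-world
  stress environments are out of scope.
* Simulation sizes used throughout (11-year weather records, ~500-cell
  grids, 10-station selections) were chosen as the smallest problems
  that exercise every code path with realistic spatial and temporal
  structure.
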