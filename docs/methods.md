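# Methods

This note documents the models, parameters, numerical choices and
limitations of `soiln2o`, in the package's own terms. Nothing stated
here as an empirical outcome is asserted beyond what the test suite and
the analysis drivers themselves compute.

## 1. The synthetic world

The generator (`soiln2o.synthgen`) emulates the statistical structure a
continental assessment draws from real sources — a topsoil point
survey, agricultural statistics, gridded daily weather, deposition
fields and alternative soil-property grids — without reproducing any of
them. Defaults describe a 12-region world (3 countries × 4 NUTS2-like
box regions, latitudes 37–61°).

* **Soil points.** SOC is log-normal per land use (arable median
  16 g kg⁻¹, log-sd 0.6; grassland median 32 g kg⁻¹, log-sd 0.9 — the
  grassland topsoil is richer, and the cohort distribution is
  right-skewed). Both medians are rescaled by one common factor, solved
  by bisection, so that the probability of exceeding the 200 g kg⁻¹
  (20% by mass) organic-soil threshold equals a configured 1.1% —
  the exclusion fraction the downstream filter then realizes. Texture
  triplets are Dirichlet draws around regional means and sum to 100
  exactly; pH ~ N(6.3, 0.9) clipped to [3, 10]; coarse fragments
  Rv ~ 60·Beta(1.3, 6) percent.
* **Weather.** Daily mean temperature = latitude lapse (32 − 0.45·lat)
  plus a sinusoid peaking mid-July (amplitude 9 °C) plus N(0, 2.5)
  noise; tmax/tmin straddle the mean by a fixed 9 °C diurnal range, so
  tmax ≥ tmin holds by construction. Precipitation is Bernoulli wet
  days (p = 0.33) with exponential intensities whose mean is set by the
  regional annual target (450–945 mm, drier south) — hence the 30-year
  mean annual total is unbiased, which a 3-standard-error test checks.
* **Regional statistics.** Crop shares are Dirichlet over the 13
  supported arable crops; livestock density, irrigated share, areas and
  deposition are bounded uniform/Beta draws. National mineral-N totals
  are area × 75 kg N ha⁻¹, identical across all regions of a country by
  construction.
* **Predictor grids.** Point predictor values are inverse-distance
  interpolated (k = 8 neighbours; k = 1 gives exact nearest-neighbour
  fields for degeneracy checks) onto a north-up raster with a
  region-ID band, plus optional white noise. The MT2 variant reuses the
  identical MT1 noise stream and rescales only the SOC-stock and clay
  layers by a configurable bias (default 1.3 / 1.1), emulating
  substitution of an alternative gridded soil product. Grids are plain
  arrays in memory and ESRI ASCII text on disk; no GeoTIFF dependency
  is available in the supported environment, and no reprojection is in
  scope.

What a green test does **not** establish: realism of any absolute
magnitude, spatial autocorrelation of soils or management (points are
independent draws), inter-annual weather trends, or survey design
effects (points are uniform within regions).

## 2. Input derivation

* **Exclusion.** Points with SOC > 200 g kg⁻¹ are removed before
  simulation (process parameterizations for mineral soils fail on
  organic soils); both partitions preserve order.
* **Hydraulics.** Field capacity, wilting point and saturated
  conductivity come from Saxton–Rawls-type regressions on clay/sand
  fractions and organic matter (OM% = SOC/10 × 1.724, clamped to the
  0.1–8% calibration range for the retention terms only). Retention
  points are then ordered defensively inside the pore space
  (wp < fc < porosity − 0.02). Volumetric retention is stone-corrected
  by (1 − Rv/100).
* **Bulk density.** Adams-type organic/mineral mixing,
  BD = 100 / (OM/0.224 + (100−OM)/BDmin) with
  BDmin = 1.45 + 0.005·sand — strictly decreasing in SOC, clamped to
  [0.5, 2.2] g cm⁻³ with a log warning.
* **SOC stock.** soc/1000 × BD × depth × (1 − Rv/100) × 100 Mg C ha⁻¹,
  over the 0–20 cm survey depth.
* **PTR.** The passive:total SOC ratio would come from a long-spin-up
  model map in a full application; here it is spatially variable,
  uniform 0.30–0.60 per point (seeded), with 0.45 as the scalar
  default. A constant PTR would degenerate one of the 12 emulator
  predictors.
* **Management.** Each arable point samples one crop per year from the
  regional shares (so 10⁴ sampled rotation-years reproduce the shares
  within a chi-square test); grassland points get permanent grass.
  Manure N = livestock density × 85 kg N LSU⁻¹ yr⁻¹, applied each
  spring half mineral / half organic (C at C:N 15). Mineral N is
  partitioned from the national total proportionally to the agronomic
  requirement of each point's rotation (per-crop requirements in the
  crop table; grassland 80 kg N ha⁻¹ yr⁻¹), with a single national
  scale factor — so the assigned mass equals the national total
  exactly. Each year's allocation is split over two events, at growth
  start and mid-season. Two tillage passes (primary mouldboard 10 days
  before planting, secondary at planting) raise decomposition 25% for
  30 days.

## 3. The daily soil core

A deliberately simplified stand-in for a full daily biogeochemistry
model; the design constraint is to preserve the mechanistic contract —
fluxes dominated by SOC (substrate) and N availability — with strict
conservation, not to reproduce any particular code's numerics.

* **Hydrology.** Four 5-cm layers. Infiltration cascades top-down;
  water above saturation passes immediately, water above field capacity
  drains at min(1, ksat/thickness) per day — so fine-textured soils
  linger above field capacity and reach high WFPS. Drainage below the
  profile leaches NO₃⁻ (efficiency 0.3 × drainage fraction).
  Evapotranspiration demand is 0.5 + 0.16·T mm day⁻¹, supplied from
  water above wilting point (max 22% of the transpirable store per
  day). WFPS = profile water / stone-corrected pore volume.
* **Soil temperature.** Per-layer relaxation toward daily mean air
  temperature (rates 0.24…0.075 day⁻¹, shallower faster).
* **SOM.** Active/slow/passive pools with base rates 7, 0.2 and
  0.0045 yr⁻¹, modified by Q10 = 2 (reference 20 °C, hard off below
  −2 °C) and a relative-water-content factor that declines again above
  WFPS 0.8. Respired fractions 0.60/0.55/0.55; the active remainder
  goes to slow except a clay-diverted share (0.004·clay%, cap 0.4)
  stabilized straight into passive; slow sends 8% of its remainder to
  passive. Pools carry explicit C and N; receivers demand N at target
  C:N (8/12/10), the net against donor N flow mineralizes to NH₄⁺ or
  immobilizes from it (capped at availability, receipts scaled down —
  conservation is exact by construction).
* **Nitrification.** NH₄⁺ × 0.10 day⁻¹ × Q10 × Gaussian WFPS response
  (optimum 0.55, width 0.28) × pH sigmoid (midpoint 6.0, slope 1.2).
  Of the nitrified flow, 1.0% leaves as N₂O-N and 1% as NOₓ-N; the
  rest becomes NO₃⁻.
* **Denitrification.** Zero at WFPS ≤ 0.60; above, NO₃⁻ × 0.08 day⁻¹ ×
  s² (s the scaled excess WFPS) × C limitation co2/(co2+18) on the
  day's heterotrophic respiration × Q10. The N₂O share of the
  denitrified flow is 0.55 × NO₃/(NO₃+18) × exp(−1.6·s): wetter soil
  reduces more completely to N₂.
* **Plants.** Daily potential growth = potential production / season
  length, shaped by a Gaussian temperature response (width 14 °C) and
  water status; realized growth is capped by accessible mineral N
  (30% of the pool per day) plus symbiotic fixation (soybean, pulses)
  at the crop C:N. Harvest removes the harvest-index share of biomass
  as yield; the rest becomes litter (45% to the active pool). Grass is
  cut twice (days 150/230, 55% removal) and its standing biomass
  enters litter at season end. The potential-production coefficients in
  the crop table were calibrated once against the package's own
  synthetic world so cohort NPP falls in the 2–5 Mg C ha⁻¹ yr⁻¹ range
  and mean fluxes land near 2 kg N ha⁻¹ yr⁻¹; they are ordinary
  config, not fitted to any acceptance check.
* **Reporting.** Simulations span 2009–2014; the first year is spin-up
  for the fast pools and is excluded from every reported quantity. The
  per-point flux used downstream is the mean over post-spin-up years
  (a single-year rule is selectable); annual sums use true calendar
  day counts, leap years included.

**Mass balance.** Every N flow (fertilizer, manure, deposition,
fixation in; N₂O, N₂, NOₓ, leaching, harvest out) and C flow (growth,
manure in; heterotrophic CO₂, harvest out) is tallied when applied;
annual residuals against pool-storage change must stay below 10⁻⁶ of
throughput (observed: ~10⁻¹³, i.e. float64 rounding).

**Vectorization.** The engine advances a whole batch (points ×
replicates) through each day in single array operations. Because every
operation is elementwise over the batch, batched and one-at-a-time
execution agree bit-for-bit — which the suite asserts — and a
50-replicate ensemble costs barely more than one run.

## 4. Monte-Carlo uncertainty

Only two inputs are perturbed (mirroring the uncertainty treatment this
workflow is built around): mineral-N events (multiplier mean 1,
**variance** 0.2) and PTR (multiplier mean 1, **sd** 0.2). The
dispersion-convention asymmetry is preserved exactly as stated rather
than harmonized. The default family is a normal truncated below at
0.01; the pre-truncation parameters are solved (2-D root find on
truncated moments) so the realized mean and dispersion match the stated
values; a log-normal family with closed-form matching is available.
Per-replicate seeds derive from (master seed, CRC32 of point id,
replicate index), so results are independent of execution order and
batch composition. The per-point uncertainty metric is the ensemble sd
(2σ and CV are also emitted). Weather, deposition and pedotransfer
coefficients carry no uncertainty here by design.

## 5. Emulator

`RandomForestRegressor` (500 trees, ⌊p/3⌋ features per split, unlimited
depth, seeded; all configurable) on the 12 predictors, 75/25 random
split. Variance explained = 100·(1 − MSE/Var(y)) with population
variance; %IncMSE importance permutes each column (default on the
held-out set; the permutation count and a permuter hook are exposed —
the identity permutation yields exactly 0). The training target is the
Monte-Carlo ensemble mean where an ensemble was run, else the
deterministic flux; both are supported because the choice is not fixed
by the workflow this emulates.

Known behaviour: with heavy-tailed SOC, held-out variance explained is
sensitive to whether the single most extreme point lands in the test
split (observed range roughly 73–87% across splits at 3000 training
records); cohort size, not tuning, is the lever that stabilizes it.
Clay and SOC stock are consistently the top two predictors, in an order
that can swap between seeds.

## 6. Upscaling and accounting

Direct route: regional mean point flux × agricultural area (regions
without points are excluded and listed, never imputed). Meta-model
route: per-cell forest prediction on the grid stack (no-data outside
the region mask), arithmetic zonal mean per region, × area. The two are
compared by Var_n = (MT_n − LCS_n)/LCS_n·100 and classified against
±20% and ±50% bands (counts partition the region set; the outer band is
a subset of the inner exceedances). Units: kg N₂O-N ha⁻¹ yr⁻¹ × ha →
kg → Tg (10⁹ kg); CO₂-equivalents multiply N₂O mass (×44/28) by a
100-year GWP of 265. Rates are reported to 2 decimals, totals to 1.

Yield validation converts reported fresh yields → dry matter (per-crop
moisture) → carbon (×0.45) and computes RMSE and MAE over matched
(region, crop) pairs.

## 7. Numerical and design choices

* Degenerate inputs: empty soil gives zero fluxes; dispersion 0 gives
  exactly the deterministic run; bias 1.0 makes MT2 identical to MT1;
  identity permutation gives importance 0; these are asserted, not
  assumed.
* Femtogram-scale negative pools from floating-point cancellation are
  clipped to zero (error ≪ the 10⁻⁶ balance tolerance); any negative
  beyond −10⁻⁶ or non-finite value aborts the run naming the process.
* CO₂-equivalent linearity holds to 10⁻¹² relative (floating-point
  rounding prevents literal bit equality of a·k + b·k and (a+b)·k).
* The degenerate grid-consistency check uses k = 1 interpolation, zero
  noise and a non-bootstrap forest (which interpolates its training
  set); with k > 1 the interpolation smooths a skewed field through a
  convex response and regional deviations of 10–15% appear — that bias
  is a property of smoothing, not an accounting error.
* Region inclusion in comparisons: present in both routes with a
  positive point mean; dropped and logged otherwise.

## 8. Limitations

No phosphorus/sulfur cycling, CH₄ oxidation, freeze–thaw emission
bursts, radiation-driven photosynthesis, rooting dynamics, or spatial
autocorrelation of inputs. The simulator is a desk-scale process core:
suitable for testing the pipeline's statistical machinery and
conservation properties, not for site prediction. Absolute totals scale
with the synthetic world's 12 regions and configured areas and are not
comparable to continental inventories.
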