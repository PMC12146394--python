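# Methods

This note documents the model, its numerical choices, the synthetic study
conditions, and what the shipped tests do and do not establish.

## The growth model

The engine is a daily radiation-use-efficiency (RUE) crop model in the
EPIC/ALMANAC tradition, deliberately reduced to the processes the pepper
analysis exercises.

**Phenology.** Daily heat units are `max(0, (Tmax+Tmin)/2 − TG)` capped at
`TB − TG` (TG = 10 °C base, TB = 30 °C optimum for pepper); their running
sum over the potential heat units PHU gives the heat-unit index HUI ∈ [0, 1],
the model's development clock. The cap means that once the daily mean
exceeds the optimum, development saturates rather than accelerating without
bound — the standard degree-day choice when only two cardinal temperatures
are calibrated.

**Canopy.** Potential LAI follows the logistic form
`f(x) = x/(x + exp(l1 − l2·x))` of HUI. The two coefficients are solved
exactly from two anchor points via the linearization
`ln(x(1−y)/y) = l1 − l2·x`; anchors are stored as packed point-codes
(integer part = percent of season or plants m⁻², two fraction digits =
percent of maximum). The ceiling is `DMLA` times a population factor — the
same logistic family through the two PPL point-codes, evaluated at plant
density. Daily LAI gain is the potential S-curve increment times the stress
factor REG; after the `DLAI` fraction of the season LAI declines linearly
in `(1 − HUI)/(1 − DLAI)` (exponent 1) from its value at decline onset.
Greenhouse runs use `DLAI = 0.99` (harvests there happened during active
growth); field runs use 0.9.

**Growth and yield.** Intercepted PAR is `0.5·srad·(1 − exp(−k·LAI))`
(Beer's law, PAR as half of global radiation, extinction coefficient
`k = 0.65`); biomass gain is `WA · IPAR · REG` with REG the *minimum* of
the temperature, water and nitrogen stress factors — never their product.
Yield is `HI_realized · biomass`, where the realized harvest index ramps
linearly with HUI from `hui_flower = 0.30` to the full HI at maturity; this
lets mid-season trial harvests carry a proportionally smaller index without
modelling individual fruits. `k` and `hui_flower` are not derivable from
the trial data; they are standard values for dense annual canopies and are
exposed in the parameter registry.

**Temperature stress** is `sin((π/2)·(Tavg−TG)/(TB−TG))` clamped to [0, 1]
on the relative range [0, 2] and zero outside — the classic sine response:
zero at base, 1 at optimum, symmetric decline above.

**Water.** A single-layer plant-available bucket (default capacity 80 mm,
30 mm at spring transplanting). Evaporative demand is radiation-based
Hargreaves, `0.0135·(Tavg+17.8)·srad/2.45` mm, split into canopy
transpiration (`×(1−e^{−k·LAI})`) and bare-soil evaporation
(`×e^{−k·LAI}`, supply-limited by relative bucket content). The water
stress factor is relative content over a 0.5 critical fraction, clamped to
[0, 1]; auto-irrigation adds 25 mm whenever the factor falls below the
trigger (default 0.85; 0 disables irrigation).

**Nitrogen.** Crop demand follows an exponential dilution curve
`a + b·exp(−c·HUI)` solved exactly through the BN1 (emergence) and BN3
(maturity) anchors, and through BN2 at HUI = 0.5 whenever
`BN2 − BN3 < BN1 − BN2` (true for all four shipped sets; otherwise the
midseason residual is minimized). Supply is a season total released
linearly over a *calendar* window (default 120 kg ha⁻¹ over 150 days),
which is what drip fertigation physically does. This calendar/heat-unit
mismatch is deliberate: under warming the crop develops faster than its
fertigation schedule and can outrun the supply — the mechanism behind
warming-induced nitrogen stress, which a supply released pro-rata with HUI
could never produce (supply would track demand timing by construction).
With the shipped non-limiting default the N machinery is quiescent in the
scenario runs; the mechanism is exercised in tests with a binding 55 kg ha⁻¹
supply, where +5 °C raises mean N-stress days (e.g. 42 → 51 on the central
band) for an identical parameter set.

## Parameter sets and field adjustment

The registry holds the four calibrated sets (PHR18/PHR23 × control/heat)
from the two-year greenhouse trial. For open-field simulation, WA drops
from 33 to 27 for PHR18-control — the ratio established by the field
calibration experiment — and the other sets scale by the same 27/33,
rounded to two decimals; only the PHR18-control ratio was measured, so
proportional scaling is the minimal assumption. `DLAI` becomes 0.9. Site
PHU values are calibrated per location by matching simulated to measured
yield (grid search, 1200–3500 by 50, ties to the smaller PHU; the search
objective is yield, not phenology dates, because the survey recorded
yields). The field `WA` estimator is the same search over WA.

## Calibration procedures

- **Kjeldahl total N** (g kg⁻¹): `(mL_sample − mL_blank) × normality ×
  14.01 / sample_mass` — titre volume × eq L⁻¹ gives meq, × 14.01 mg/meq
  gives mg N, over g of sample gives g kg⁻¹.
- **Harvest index**: fruit over total above-ground mass, reported to two
  decimals (the trial's precision).
- **Leaf-area curve fitting**: observed LAI is normalized by the canopy
  ceiling, the linearized S-curve is fit by least squares over growth-phase
  points, and the fitted curve is re-encoded as point-codes at canonical
  abscissae (observed fraction nearest 10 % of the season; the abscissa
  whose fitted ordinate is nearest 95 % of maximum). Exact two-point input
  reproduces its generating codes. When the ceiling must itself be
  estimated from data, the plateau observation is treated as 95 % of
  maximum — the same convention the second point-code encodes.
- **BN2/BN3**: total N over dry biomass at the stages nearest HUI 0.5 and
  1.0 (the trial's two harvests), to three significant figures.

## Synthetic study conditions

All inputs are generated, none downloaded.

- **Greenhouse weather**: day/night setpoints (28/18 °C control, 30/22 °C
  heat, 77-day treatment window) with optional Gaussian jitter, constant
  18 MJ m⁻² d⁻¹ radiation.
- **Open-field weather**: three latitude bands (northern/central/southern
  Korea analogues). Daily mean temperature is a sinusoid (January/July
  means per band, mid-July peak) plus AR(1) anomalies (sd 2.2 °C, lag-1
  correlation 0.7) shared by Tmax/Tmin; radiation is a solstice-peaked
  clear-sky curve damped 55 % on rain days; precipitation is Bernoulli
  occurrence with a *squared* seasonal weight — concentrating rain in the
  summer monsoon and leaving spring comparatively dry, as in Korea — with
  exponential amounts (annual total ≈ 1400 mm, May ≈ 3 mm d⁻¹).
- **Sites**: nine synthetic sites mirror the survey's provinces; their PHU
  values (1500–1800) follow the survey's regional pattern (cool mountainous
  northeast low, south high) but are assigned, not measured.
- **Trial observations**: the engine's own trajectory sampled at the trial
  measurement days, plus Gaussian noise whose per-variable defaults are the
  medians of the published ± dispersions (LAI 0.63, total fresh mass 249 g,
  fruit 151 g, …), treated as standard deviations. Invariant violations
  (fruit > total, moisture outside [0, 100]) are clamped, not resampled, so
  a seed always yields the same records.
- **Titrations and site yields**: exact inverses of the Kjeldahl equation
  and the engine, plus seeded noise — the ground truth for recovery tests.

What passing tests show, and what they do not: recovery tests demonstrate
that the calibration chain inverts the model on data the model itself
generated (internal consistency). They say nothing about how well the model
fits real pepper physiology — the published trial and survey tables enter
only through their *reporting arithmetic* (harvest indices, percent
differences, ratios, RMSE/PBIAS), which the package reproduces exactly from
the printed values. The synthetic generators also omit known features of the
real campaign: disease pressure (which depressed the second trial year),
heat spikes above 40 °C inside the greenhouses, and any correlation between
temperature anomalies and rainfall.

## Scenario design

Baseline: ten generated years per site, control-condition field parameters,
site PHU. Warming: the same years with Tmax and Tmin raised uniformly by
3/4/5 °C and the *heat*-condition field parameter set (front-loaded canopy
curve, heat PPL codes, lower WA scaled by 27/33), keeping the site PHU —
warming perturbs the weather, not the site's heat requirement. Yields are
averaged over years; percent changes use round-half-away-from-zero (the
convention that reproduces the published −32 from −31.5).

On this configuration every site loses yield under every warming level for
both accessions, maturity advances by roughly two months at +5 °C, and mean
irrigation demand rises — the qualitative pattern of the published
analysis. The loss *magnitudes* run steeper (≈ 67–83 %) than the published
31–54 %, mostly because the heat-condition plant-population codes cut the
canopy ceiling sharply at the 2.5 plants m⁻² field density; magnitudes are
therefore not asserted anywhere, only orderings.

## Numerical and reporting conventions

- Point-codes decode through integer hundredths, so `10.19` can never
  decode as `(10, 0.18999…)`; codes with zero fractional digits are
  rejected (a zero ordinate is inadmissible on the logistic).
- Grid searches break ties toward the smaller candidate; malformed ranges
  and all-failing grids raise instead of returning a guess.
- PBIAS keeps its sign internally (positive = model underestimates); the
  magnitude is reported. R² is the squared Pearson correlation and is
  flagged undefined under zero variance.
- Every stochastic entry point takes one integer seed; batch runners derive
  per-site/per-year seeds from it, so whole reports are byte-reproducible.
- Output CSVs start with a provenance comment (package version, seed,
  config hash).

## Known limitations

- One published scenario-table cell (PHR23, Hamyang, +5 °C) prints a −48 %
  loss that cannot be recomputed from its two printed yields (−47.47 → −47);
  it was evidently computed before yield rounding and is flagged as
  inconsistent in the packaged table rather than silently matched.
- The engine has no photosynthesis biochemistry, CO₂ response, disease
  coupling, soil-layer or root detail, photoperiod or vernalization.
- The harvest-index ramp is a simplification of drought-adjusted harvest
  index accounting; it is exact at maturity and linear in HUI before it.
- Greenhouse simulated yields depend on unpublished in-house weather in the
  original campaign; the package treats the published greenhouse yield
  values as plausibility context only and does not attempt to reproduce
  them.
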