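# Methods

This note documents the model equations, the defaults, the numerical
choices, and the points where the design was genuinely open. Anything
quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted that the code does not
reproduce.

## Thermal time and growth

Daily thermal time uses the mean temperature `Tmean = (Tmin + Tmax)/2`:
zero at or below *Tbase* (10 °C) and at or above the cut-off *T_M2*
(38 °C); otherwise `min(Tmean, T_M1) − Tbase` with *T_M1* = 33 °C. Applying
the caps to the daily mean (rather than the daily maximum) was an open
choice; the mean was adopted because it makes accrual monotonically
non-decreasing in *T_M2*, which the in-season adjustment requires
(raising the cut-off must never slow the simulated crop).

Potential shoot biomass is `SDW(tt) = β₁/(1 + exp(β₂ + β₃·tt))` with the
defaults β₁ = 12.2874 t/ha, β₂ = 6.0894, β₃ = −0.0096 °Cd⁻¹: asymptote
12.29 t/ha, inflection at ≈634 °Cd, intercept ≈0.028 t/ha (≈1 g/plant at
2.9 plants/m²) — transplant scale. The daily increment is the logistic
difference at the current *expected* asymptote, multiplied by the same-day
water and N stress factors, and additionally capped at
`expected_β₁ − SDW`. The cap matters only after an in-season or N-budget
adjustment has lowered the expected asymptote: without it the increments of
a freshly lowered curve would carry the state past its own asymptote, and
"zero remaining N budget" would not actually freeze growth.

The lag phase applies a constant areal increment `Plts_GR · density`
(0.015 g/plant/day) until the logistic daily increment first exceeds it.
With the default parameter set the logistic increment exceeds the lag
increment from the first day, so the lag branch is dormant; it engages for
parameter sets with slower early logistic growth (it is exercised that way
in the tests). Seedling mass at transplanting (0.5 g/plant by default,
0.2 g/plant for younger transplants) sets the initial biomass.

Maturity: at `tt ≥ TSMax` (1660 °Cd), or past `TSMin` (1300 °Cd) after
*d_SDWstop* = 10 **consecutive** days with increments below 1% of β₁ per
day. A cumulative counter would trip the moment `TSMin` is crossed, because
early-season increments are also small; consecutiveness makes the rule mean
"growth has stopped", which is its agronomic intent.

Flowering heat stress is tallied when the thermal sum lies in
[*Flw_beg*, *Flw_beg* + *Flw_dur*) = [250, 500) °Cd and Tmax strictly
exceeds *Flw_Tmax* = 40 °C (the window's upper bound was taken exclusive,
the temperature threshold strict). Stress days reduce fresh yield only —
1% per day by default, configurable — not biomass: heat during flowering
damages fruit set, which the harvest-index conversion, not the growth
curve, should carry.

Fresh yield: `TFY = SDW·HI/(YldSDW/100)` with HI = 0.66 and 5.5% fruit dry
matter, capped at the expected per-plant yield (5300 g/plant × density).

## Soil water

A single root-zone bucket. Root depth ramps linearly from 5 cm at
transplanting (the starting depth is not a literature value; 5 cm is a
plausible plug-transplant depth) to 40 cm at 45 days. Soil newly explored
by root growth enters at the initial water content. TAW =
`(FC − WP)·depth·10` mm; RAW = 40% of TAW.

Daily step (supply first, FAO-56 daily convention): today's rain and
irrigation reduce depletion before the stress factors are evaluated, so an
irrigation relieves stress the day it is applied. `Ks = 1` while depletion
≤ RAW, declining linearly to 0 at TAW. Soil evaporation uses a single-stage
coefficient `Ke = (Kc − Kcb)` damped linearly by bucket dryness — a
deliberate simplification of the two-stage FAO-56 evaporation model, chosen
because the stage-wise Kc/Kcb triplets are the only available controls.
Actual ET is capped so the bucket never overdraws; excess water drains.
The water ledger closes to 10⁻⁶ mm over arbitrary forcing (property-tested).

Irrigation scheduling refills depletion to field capacity whenever it
reaches RAW, scaled by the drip wetted fraction
`min(1, density·π·r²)` from the maximum wetted radius (30 cm) — the only
role given to that radius parameter.

The 10–30 cm volumetric water content is reported assuming the deficit is
uniform over the root zone (`θ = FC − depletion/(10·depth)`, clamped to
[WP, FC]); no vertical profile is modelled.

## Nitrogen

Critical N concentration `Nc(%) = a·W^b` with a = 4.53, b = −0.327
(an alternative local calibration a = 3.91, b = −0.173 is configurable),
held constant at `a` below 1 t/ha — the standard plateau of the critical-N
dilution literature, which also removes the `W^b` singularity at zero
biomass. Cumulative demand `W·10·Nc(W)` is strictly increasing and
continuous; daily demand is its difference along the (water-limited) growth
increment.

Mineralization: the SOM-N stock of the rooted layer
(`depth·100·ρb·SOM%·5.8% N`) releases 2%/year at 20 °C with Q10 = 2 and
zero release at or below 0 °C. All four constants are configurable; the
defaults give ≈0.23 kg N/ha/day at 20 °C for 1.4% SOM over 40 cm —
tens of kg per season, linear in SOM, which is the behaviour the scenario
analysis needs. Leaching assumes complete mixing of mineral N in root-zone
water: the leached fraction equals drainage over root-zone water. Uptake is
`min(demand, pool − reserve)` with phase reserves 3/20/10 kg/ha
(initial/mid/final, phases delimited by the stage-table days); the reserves
act both as an uptake floor and as a scheduling target — the two readings
are consistent and both implemented. The N ledger closes to 10⁻⁶ kg/ha.

The fertigation scheduler runs daily: it sizes an event to cover a 7-day
forecast of demand (projected along the logistic at the recent mean thermal
time) plus the phase reserve, net of the current pool, topped up by the
same-day complete-mixing leach fraction so that a storm on a fertigation
day does not strip the pool below the crop's needs. In NVZ mode the event
is truncated so cumulative fertilizer never exceeds 170 kg/ha — a hard
constraint, property-tested — and the simulator then solves
`cumulative_demand(W*) = cumulative_demand(SDW) + remaining budget` (budget
= remaining cap allowance + available pool + forecast mineralization over
the remaining cycle) by bracketed root finding and lowers the expected
asymptote to W*. This is the adaptive-potential control: under a binding
cap the crop grows to a smaller, N-consistent final biomass instead of
running into acute deficiency.

## In-season growth check

At the sampling nearest one third of the cycle length (clamped to the
30–50 DAT window), `CheckPO = predicted/observed`. Two ratio polynomials —
3rd order for `newT_M2/T_M2`, 2nd order for `newβ₁/β₁`, both functions of
CheckPO — adjust the parameters from the check day onward. The package
ships its own calibrator for these polynomials; the historical shape
coefficients printed for a legacy implementation are stored verbatim
(`LEGACY_SHAPE_COEFFICIENTS`) but never used, because their
parameterization (orientation, normalization, intercepts) is not
recoverable: a 3rd-order polynomial needs four coefficients and the printed
pair for the biomass ratio does not anchor at 1 for CheckPO = 1. The
shipped defaults are mild first-principles corrections (β₁ scaled by
≈1/CheckPO — the exact inverse of a proportional miss — and a 15%-of-miss
nudge on the cut-off temperature), anchored exactly at CheckPO = 1.

Calibration per trial: the best-fit β₁ against post-check samplings is
closed-form (the model is linear in β₁ for fixed kernel); the best-fit
cut-off temperature is a bounded 1-D search (both directions allowed) with
the re-accrued thermal times, kept at the baseline when the objective is
flat in *T_M2* (weather that never approaches the cut-off leaves it
unidentified). Ratio polynomials are then fitted across trials with the
anchor point (1, 1) at ten-fold weight, so the identity property holds by
construction; a degenerate collection (all CheckPO ≈ 1) returns constant-1
polynomials. The polynomial degrees shrink to the number of distinct
abscissae when a collection is small. Applied corrections are additionally
clamped never to *decrease* β₁ on under-prediction and never to push
*T_M2* below *T_M1*.

## Logistic fitting

`fit_logistic` solves the nonlinear least-squares problem with
Levenberg–Marquardt (damped Gauss–Newton; `scipy.optimize.least_squares`,
relative tolerances 10⁻⁸, iteration cap 200·4 evaluations). Starting values
are data heuristics: β₁ = 1.05·max(SDW), β₂/β₃ from the log-linearized
logistic. The fit is deterministic given the data, scale-consistent
(scaling observations scales β₁ only) and recovers noise-free synthetic
parameters to 4 decimals; under 5% multiplicative noise the median β₁
error across 200 replicates stays below 5%.

## Evaluation statistics

RMSE, RRMSE (% of observed mean), RSR, MAE, PBIAS and NSE per their
standard definitions, with two printed-source quirks resolved
deliberately: MAE is the mean *absolute* error (the signed variant, a mean
error, is exposed separately as `mean_signed_error`), and RSR divides RMSE
by the square root of the observed sum of squared deviations (not the
standard deviation) — the convention consistent with the magnitudes such
reports print. RRMSE quality classes use half-open intervals:
[0, 10) excellent, [10, 20) good, [20, 30) fair, ≥30 poor. Degenerate
inputs (length < 2, length mismatch, constant observations) raise specific
diagnostic errors rather than returning NaNs.

## Synthetic weather

The generator emulates two station climatologies with a six-parameter
profile: annual-sinusoid mean temperature (mean, amplitude, peak day) with
i.i.d. Gaussian daily anomalies, a fixed diurnal range split symmetrically
around the mean, and rain as an independent Bernoulli/exponential process.
Defaults: Mediterranean (mean 16.5 °C, amplitude 9.5 °C, range 12 °C,
anomaly sd 1.8 °C, wet-day frequency 0.12, wet-day mean 6 mm, transplant
10 May) and humid-subtropical (21.5 °C, 7 °C, 11 °C, 1.6 °C, 0.25, 8 mm,
mid-March). These were chosen once as realistic for the two production
regions the simulator targets. What the generator does **not** emulate:
temperature autocorrelation and heat waves, seasonal rain clustering,
humidity/wind/radiation coherent with temperature (so synthetic series
exercise the Hargreaves ET path, not Penman–Monteith). Consequently,
passing tests demonstrate internal consistency and the scheduler's
closed-loop behaviour under plausible forcing — not predictive skill on
real station data, which requires site calibration.

The scenario runner uses one bundled Mediterranean season (160 days, seed
20150710). Under it the default crop matures at 91 DAT — inside the
90–120 DAT band such trials span — and the 2×2 SOM × NVZ grid reproduces
the qualitative pattern the scenario analysis is about: non-NVZ outcomes
independent of SOM with fertilizer input decreasing in SOM; NVZ outcomes
capped at exactly 170 kg/ha with uptake and yield below the non-NVZ cells
and increasing in SOM. The absolute scenario numbers depend on the weather
and soil chosen and are not comparable to any particular published run.

## Numerical choices and degenerate inputs

- Root finding for the N-budget inversion: `brentq` on [current SDW, β₁],
  xtol 10⁻⁹; budget 0 short-circuits to the current biomass.
- Water-balance closure is exact by construction (drainage absorbs bucket
  underflow, ET is capped at availability); ledgers are floats, tested to
  10⁻⁶.
- `ETc = 0` returns a water-stress factor of 1 (no transpiring surface, no
  stress); `demand = 0` returns an N factor of 1.
- Degenerate stage ramps (t1 = t2) step directly between values.
- Initial mineral N defaults to 30 kg/ha — typical residual nitrate for an
  intensively cropped Mediterranean soil at spring transplanting; it is a
  configuration value, not a fitted one.
- Seeds: every stochastic routine takes an explicit seed; simulations
  themselves are deterministic.

## Problem sizes

Tests and the acceptance script run synthetic seasons of ≤160 days, trial
collections of 4–5 trials × 7 samplings, 200-replicate fit studies and
1000-series statistics sweeps; the full suite completes in a few seconds.
These sizes were chosen as the smallest at which every asserted property is
stable across seeds.

## Known limitations

- Single-bucket soil water and single-pool mineral N: no layered profile,
  capillary rise, runoff, nitrification/denitrification/volatilization, or
  ammonium/nitrate speciation.
- No radiation-interception or leaf-area growth model; biomass depends on
  thermal time only, so genotype and management differences enter solely
  through the parameter file and the in-season check.
- Seepage irrigation and plastic-mulch ET modifiers are accepted in the
  configuration (mulch as percentage Ke/Kcb modifiers, default off) but the
  refill logic models drip systems only.
- The fresh-yield flowering-stress coefficient (0.01/day) is a modelling
  device, not a calibrated value.
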