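# Methods

## Degree-day computation

Daily DD are computed by the single sine method: one sine period is
fitted to the day's tmin/tmax (no blending with the next day's tmin)
and the area between the lower developmental threshold (7.2 °C) and
the curve is integrated, with a **horizontal cutoff** at the upper
threshold (30 °C) — accumulation above 30 °C is capped, not
subtracted.  Writing *m* for the daily mean, *A* for half the diurnal
range and clipping both arcsine arguments to [−1, 1],

    DD = [ (m−L)(θ₂−θ₁) + A(cos θ₁ − cos θ₂) + (U−L)(π/2 − θ₂) ] / π,
    θ₁ = asin(clip((L−m)/A)),  θ₂ = asin(clip((U−m)/A)),

which collapses the six classical interception cases (below / within /
above / lower- / upper- / doubly-intercepted) into one continuous
expression; the test suite verifies agreement with direct quadrature of
the clipped sine to well below 10⁻⁶ °C·day and continuity across every
case boundary.  The cutoff variant and the day-level convention are
deliberate dialect choices — other dialects (double sine, triangle,
next-day blending) give slightly different numbers and are out of
scope.

Oviposition is permitted on a day when its **daily mean** lies inside
the reproductive band 13.4–29.3 °C.  The mean is the simplest
day-level representative; an "overlap" alternative (any part of the
sine excursion intersects the band) is available via the `statistic`
argument of `reproduction_permitted` for sensitivity analysis.

## Vital-rate calibration

The survival and maternity curves are reported with parameters on an
unstated normalised age axis: Gompertz (a = 5.3, b = 1.5) applied to
raw DD would underflow (exp(5.3·610) overflows), and a Cauchy located
at 1 with scale 1.9 cannot peak at 410 DD.  The package therefore
treats those printed values as metadata and anchors the working curves
to the explicitly stated landmarks:

- **Survivorship** uses u = DD/1000.  This choice reproduces every
  stated behaviour: low immature mortality to ~200 DD
  (L(200) ≈ 0.586), a steep decline to ~400 DD, and survival < 0.5 %
  at 610 DD (L(610) ≈ 0.001).
- **Maternity** is re-expressed as a truncated Cauchy kernel
  M(x) = 15 / (1 + ((x−410)/50)²) on [210, 610) DD.  The three anchors
  (onset 210, mode 15 eggs/DD at 410, cessation 610) are exact by
  construction; the 50 DD scale is the remaining free constant, chosen
  so onset is gradual (M(210) ≈ 0.88 < 1 egg/DD).  The kernel is hard-
  truncated and **not renormalised**: the peak height is the stated
  constraint, not the integral.  Whether maternity is per female or
  per individual is not specified; the model books females only
  (classic L·M accounting) with a configurable `female_fraction`
  (default 1.0).

Both calibration constants live in the species profile
(`data/d_suzukii.yaml`) and can be overridden.  Stage boundaries are
stored at full precision (egg→larva at 20.27 DD, resolving the
20.27/20.3 rounding discrepancy in favour of the more precise figure)
with half-open intervals, so each age maps to exactly one stage.

The extreme-condition curve (a = −0.009, b = 0.09501 over calendar
days) has a strictly positive horizontal asymptote e^{b/a} ≈ 2.6·10⁻⁵:
un-acclimated populations are decimated but not extinguished by
prolonged extremes.  It is exposed (`survival_extreme`) but **not**
invoked by the simulator, which models the growing season only; on a
zero-DD day the simulator applies no mortality at all.  Capturing
winter acclimation and phenotypic plasticity would require a coupling
between the two regimes that is deliberately out of scope.

## Simulator design

Within a day the update order is: (1) compute ΔDD; (2) management
mortality; (3) natural survival; (4) reproduction; (5) ageing;
(6) culling.  The order matters slightly (management before natural
survival) and is fixed so runs are exactly reproducible.  Survival is
applied as the conditional probability L(x+ΔDD)/L(x) on the current
size — telescoping, so splitting a day into half-steps changes nothing,
and equivalent to applying L to the cohort's initial size.  The day's
egg integral uses the midpoint rule: size × M(x + ΔDD/2) × ΔDD, summed
over cohorts whose current age lies in the reproductive span
[210, 610) DD.  Eggs recruit one new cohort aged 0 DD per day.
Cohorts are culled at 610 DD or when they fall below 10⁻⁹ of the
initial total (numerical hygiene; configurable).  The default initial
population is one adult cohort of 100 females at 200 DD age — the
overwintered, all-adult population structure at season start.

The core is deterministic and linear in abundances, which has two
consequences exploited by the tests: (i) any multiplier ≤ 1 can only
reduce the population, so treated ≤ control pointwise, and (ii) the
deterministic trajectory equals the expectation of the stochastic
individual-based process with binomial survival thinning and Poisson
recruitment at the same rates.  The individual-based implementation
(`simulate_individuals`) stores integer counts per birth cohort —
individuals born the same day are exchangeable, so binomial count
thinning is exactly per-individual Bernoulli survival — and serves as
the independent oracle: a 60-day deterministic run must sit within 3
Monte-Carlo standard errors of a 200-replicate ensemble mean.

## Management scenarios

Interventions compose multiplicatively per day and stage.

- **Insecticide A** (adult-focused): 95 % adult knockdown applied once
  on the application day (single mortality factors, not daily rates);
  immature daily mortality decays linearly 100 % → 5 % across a 10-day
  residual window (highest mortality on day 1, simulating decaying
  residual activity).  **Insecticide B** (broad-spectrum): 60 % adult
  knockdown; immature mortality 95 % → 60 % over 10 days.  The 10-day
  residual matches the upper end of reported field residual activity
  and is configurable.
- **Insecticide C** (RNAi biopesticide): for a 7-day window, egg
  production ×(1 − 0.415) and egg viability ×(1 − 0.217) (combined
  egg-output reduction 54.2 %, the product of the two components —
  the separately reported components are taken as primary where they
  disagree with a reported composite), and a 22 % larval kill over the
  window, applied as the equivalent constant daily multiplier
  0.78^{1/7} rather than 22 % per day.
- **Parasitism**: season-long; each cohort loses the parasitised
  fraction exactly once, on the day its age crosses the larva→pupa
  boundary (118 DD), so stage-level parasitism equals the nominal
  fraction by construction.  Presets at 2 % (field rates in invaded
  regions) and 15 % (native-range collections).

## Synthetic weather

`gen_weather` produces tmean(d) = mean + amplitude·sin(2π(doy −
phase)/365) + N(0, σ), with tmin/tmax = tmean ∓ range/2; all
generation is seeded.  Two presets encode the qualitative climate
features the scenario analyses need: `salem_like` (mean 11.5 °C,
amplitude 8.5, range 12) accumulates DD from early March and keeps
summer means inside the reproductive band; `parlier_like` (mean
17.5 °C, amplitude 12.5, range 15) is warm from April and has a
mid-summer stretch of daily means above 29.3 °C during which
oviposition shuts down.  The generator does **not** emulate weather
fronts, autocorrelation, heat waves or rainfall; passing tests
demonstrate correct model mechanics under realistic seasonal forcing,
not skill against any particular station record, and actual station
data can be supplied as CSV wherever a synthetic series is used.

## Fitting utilities

`fit_gompertz` estimates (a, b) by nonlinear least squares on the
surviving fractions (`scipy.optimize.curve_fit`, start (1, 1), the age
scale held fixed) and reports Pearson χ² = Σ(obs−fit)²/fit.  Constant
survival (no mortality signal) is rejected as degenerate rather than
returned as a b→0 boundary estimate.  Under binomial life-table noise
(250 individuals scored every 25 DD) the median relative error of both
parameters is below 5 % across 200 replicates.

`fit_maturity` is simple OLS of percent mature (0–100 scale, matching
the reported coefficient units) on DD from January 1, via statsmodels;
the single-predictor design matches the reported df.  Predictions are
clipped to [0, 100], which preserves monotonicity for positive slopes.
Raw dissection counts are not available, so validation is by exact-fit
recovery of the reported regional lines and by parameter recovery from
binomially sampled synthetic surveys.

## Problem sizes and numerics

The bundled analyses use full-year synthetic weather, ~120–215-day
simulation windows, a 60-day / 200-female / 200-replicate
individual-based comparison, 500-replicate maturity recovery and
200-replicate Gompertz recovery; all complete in seconds.  Floating
point: survival uses `expm1` for accuracy near a→0 (with the exact
exponential limit at a = 0); degree-days clamp tiny negative round-off
to 0; result CSVs are written at 17 significant digits and re-read
with round-trip float parsing so files reproduce memory exactly.

## Known limitations

No density dependence, host availability, humidity, spatial structure,
immigration, sex-ratio dynamics or insecticide-resistance evolution;
absolute abundances are therefore comparative indices, not forecasts.
Winter/extreme survival is not coupled to the seasonal model.  The
calibration of the normalised age axis is an interpretation anchored to
stated landmarks rather than a refit of the original data.
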