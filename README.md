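# ddcohort

A degree-day cohort population model for *Drosophila suzukii* (spotted
wing drosophila), a worldwide pest of berries and stone fruit.  The
package is for entomologists, IPM practitioners and modellers who want
to compare management tactics — adulticides, broad-spectrum compounds,
RNAi biopesticides, larval/pupal parasitism — on a *relative* scale
driven by nothing more than daily minimum/maximum temperature.

## The model

Physiological time is measured in degree-days (DD): daily heat
accumulated above the lower developmental threshold *T*<sub>L</sub> = 7.2 °C,
capped at *T*<sub>H</sub> = 30 °C, computed from tmin/tmax by the
**single sine method** (closed arcsine forms for all six threshold-
interception cases, horizontal upper cutoff).

Over DD age *x*, vital rates follow two fitted curves:

- **Survivorship** — Gompertz: *L*(*x*) = exp(−*b*/*a* (e^{*a·u*} − 1))
  with *a* = 5.3, *b* = 1.5 on the normalised age *u* = *x*/1000.
  *L*₀ = 1, mortality is low through the immature stages and survival
  is effectively zero by 610 DD.
- **Gross maternity** — a truncated Cauchy kernel *M*(*x*) =
  15 / (1 + ((*x* − 410)/50)²) eggs · DD⁻¹ · female⁻¹ on [210, 610) DD:
  oviposition starts at 210 DD, peaks at 15 eggs/DD at 410 DD, and
  ceases at 610 DD.

Life stages partition age (half-open intervals): egg [0, 20.27), larva
[20.27, 118), pupa [118, 199.9), adult [199.9, 610) DD.

The simulator steps one calendar day at a time.  Every cohort (a
same-day birth group with shared DD age χ and female abundance) ages by
the day's DD, survives with the conditional probability
*L*(χ+ΔDD)/*L*(χ), and — when the daily mean lies inside the
reproductive band 13.4–29.3 °C — contributes net maternity
*L*ₓ*M*ₓ.  The daily sum Σ *L*ₓ*M*ₓ over all reproductive cohorts
recruits a new cohort aged 0 DD.  Management scenarios supply
stage-targeted daily survival multipliers and fecundity/viability
multipliers on egg production.  A separate calendar-day Gompertz
(*a* = −0.009, *b* = 0.09501) describes survival under temperature
extremes where no DD accrue; it levels off at the strictly positive
asymptote e^{*b*/*a*} and is exposed for analysis but not wired into
the seasonal simulator.

A companion regression utility models **late-dormant reproductive
potential**: the percent of overwintered females dissected with mature
eggs as a linear function of DD accumulated from January 1.

## Worked example

```bash
python examples/insecticide_comparison.py
```

```
insecticide_a: min ratio 0.00023 (max reduction 100.0 %), season-end ratio 0.0013
insecticide_b: min ratio 0.00036 (max reduction 100.0 %), season-end ratio 0.0022
insecticide_c: min ratio 0.61 (max reduction 38.9 %), season-end ratio 0.83
```

Three single applications (April 20) on the same synthetic hot-valley
season, measured as the treated/control total-population ratio.  The
adulticide (A, 95 % adult knockdown) hits the early, adult-dominated
population hardest and keeps the treated population furthest below the
control all season; the broad-spectrum compound (B) allows faster
relative recovery; the RNAi biopesticide (C), which spares adults,
causes only a modest dip.  Likewise,

```bash
python examples/parasitism_comparison.py
```

```
parasitism 2 %: season-end population reduction 10.3 % vs control
parasitism 15 %: season-end population reduction 58.1 % vs control
```

— season-long larval/pupal parasitism compounds across generations, so
the high rate observed in the pest's native range suppresses far more
than the ~2 % field rates typical of invaded regions.  The other
examples (`degree_day_basics.py`, `life_table_curves.py`,
`season_simulation.py`, `maturity_regression_fit.py`) walk through DD
accumulation, the vital-rate curves, a control season, and the
maturity regression.

Because recruitment is linear with no density dependence, absolute
abundances grow geometrically; only comparisons between scenarios on
identical weather are meaningful.

## Command line

A thin CLI wraps the library:

```bash
ddcohort gen-weather --preset parlier_like --seed 1 --out weather.csv
ddcohort dd --weather weather.csv --start 2013-01-01
ddcohort simulate --config run.yaml
ddcohort compare --treated treated.csv --control control.csv
ddcohort fit-maturity --data dissections.csv
ddcohort profile show
```

Exit codes: 0 success, 2 input validation, 3 numerical/fit failure.

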