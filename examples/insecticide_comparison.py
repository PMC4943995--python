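"""Compare three single-application treatments on the same season.

Insecticide A: 95 % adult knockdown, immature daily mortality decaying
100 % -> 5 % over 10 days.  Insecticide B: 60 % adult knockdown,
immature mortality 95 % -> 60 %.  Insecticide C (RNAi biopesticide):
7 days of reduced egg output/viability plus a 22 % larval kill.
The metric is the treated/control total-population ratio.
"""

import datetime as dt

from ddcohort import (
    gen_weather,
    load_profile,
    make_insecticide_a,
    make_insecticide_b,
    make_insecticide_c,
    parlier_like,
    relative_impact,
    run_simulation,
)

vr, thr = load_profile("d_suzukii")
weather = gen_weather(parlier_like(year=2013, seed=1))
start, end, app = dt.date(2013, 4, 1), dt.date(2013, 7, 31), dt.date(2013, 4, 20)

control = run_simulation(weather, start, end, vr=vr, thr=thr)
for factory in (make_insecticide_a, make_insecticide_b, make_insecticide_c):
    scenario = factory(app)
    treated = run_simulation(weather, start, end, vr=vr, thr=thr, mgmt=scenario)
    ri = relative_impact(treated, control)
    print(
        f"{scenario.label}: min ratio {ri['ratio'].min():.2g} "
        f"(max reduction {ri['percent_reduction'].max():.1f} %), "
        f"season-end ratio {ri['ratio'].iloc[-1]:.2g}"
    )

print(
    "\nThe adulticide (A) hits the early, adult-dominated population hardest and"
    " keeps the treated population furthest below control; the broad-spectrum"
    " compound (B) allows faster relative recovery; the biopesticide (C) causes"
    " only a modest dip because it spares adults."
)
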