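"""Fit the late-dormant maturity line from a synthetic dissection survey.

Overwintered females are dissected through winter/spring; the percent
carrying mature eggs rises linearly with DD accumulated from January 1.
Here a survey is simulated from a known line (binomial sampling of 50
females per collection) and the line re-estimated by OLS.
"""

import numpy as np

from ddcohort import MaturityRegression, fit_maturity, gen_dissection_table, predict_maturity

true = MaturityRegression(slope=0.14, intercept=-4.55, r_squared=1.0,
                          f_statistic=np.inf, df_model=1, df_resid=0)
records = gen_dissection_table(true, np.arange(100.0, 701.0, 50.0), n_per_point=50, seed=11)
fit = fit_maturity(records)

print(f"true line:      percent = 0.1400 * DD - 4.55")
print(f"recovered line: percent = {fit.slope:.4f} * DD + {fit.intercept:.2f}")
print(f"R^2 = {fit.r_squared:.3f}, F = {fit.f_statistic:.1f} "
      f"(df = {fit.df_model}, {fit.df_resid})")
for dd in (50.0, 300.0, 700.0):
    print(f"predicted % mature at {dd:>5.0f} DD: {predict_maturity(dd, fit):.1f}")
print("\nPredictions are clipped to [0, 100]: below the line's root no females"
      " are expected to carry mature eggs yet.")
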