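# Default Drosophila suzukii species profile.
# Thresholds in degC; stage boundaries and maternity axis in degree-days (DD).
name: d_suzukii
thresholds:
  dev_low: 7.2
  dev_high: 30.0
  repro_low: 13.4
  repro_high: 29.3
stages:
  egg_end: 20.27
  larva_end: 118.0
  pupa_end: 199.9
  adult_end: 610.0
survival_dd:            # Gompertz over DD within thresholds, on u = DD / age_scale
  a: 5.3
  b: 1.5
  age_scale: 1000.0
survival_extreme:       # Gompertz over calendar days at temperature extremes
  a: -0.009
  b: 0.09501
  age_scale: 1.0
maternity:              # truncated Cauchy kernel, eggs per DD per female
  location: 410.0
  scale: 50.0
  peak_rate: 15.0
  support_lo: 210.0
  support_hi: 610.0
  printed_location: 1.0   # as-reported parameters on an unstated normalised
  printed_scale: 1.9      # axis; metadata only, never used in computation
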