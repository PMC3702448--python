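# Packaged reference configuration for the simulated healthy-volunteer cohort.
#
# Per-slice geometric-mean relaxation times (ms), multiplicative inter-subject
# scatter factors, and covariate structure of the reference cohort at 3 T.
# hr_split_means give [below-median, above-median] heart-rate group means per
# slice for the map types with a heart-rate dependence.

cohort:
  n_per_stratum: 10            # 6 strata (2 sexes x 3 age bands) -> 60 subjects
  age_bands: [[20, 39], [40, 59], [60, 80]]
  heart_rate:
    mean: 70.0                 # min^-1
    sd: 6.0
    min: 47.0
    max: 102.0
    split: 69.5                # cohort median used for the binary covariate
  blood_pressure:
    systolic_mean: 132.0       # mmHg
    systolic_sd: 12.0
    diastolic_mean: 72.0
    diastolic_sd: 11.0

reference_values:              # per-slice geometric means, ms
  t2:      {base: 44.1,   middle: 45.1,   apex: 46.9}
  t1_pre:  {base: 1157.1, middle: 1158.7, apex: 1180.6}
  t1_post: {base: 427.3,  middle: 411.2,  apex: 399.7}

scatter_factors:               # multiplicative inter-subject SD (dimensionless, >= 1)
  t2: 1.08
  t1_pre: 1.05
  t1_post: 1.11

hr_split_means:                # [below-median, above-median] group means, ms
  t2:      {base: [45.8, 42.8], middle: [46.5, 43.9], apex: [48.2, 45.7]}
  t1_post: {base: [445.7, 418.7], middle: [430.1, 405.3], apex: [427.6, 388.0]}

age_effect_t1_pre: 0.95        # multiplicative shift for the 60-80 y band

observer:                      # Bland-Altman targets for the remeasurement generator
  t2:      {intra: {bias: 0.0, sd_diff: 1.3}, inter: {bias: 0.1, sd_diff: 1.1}}
  t1_pre:  {intra: {bias: 4.6, sd_diff: 18.3}, inter: {bias: 0.5, sd_diff: 20.2}}

acquisition:
  t2prep_times_ms: [0.0, 24.0, 55.0]
  molli_base_ti_ms: [100.0, 180.0, 260.0]   # 3-3-5 pattern, min TI >= 91 ms
  molli_group_sizes: [3, 3, 5]
  ba_ratio: 2.2
  noise_sd: 1.0                # Rician sigma, arbitrary units (tissue S0 = 100)
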