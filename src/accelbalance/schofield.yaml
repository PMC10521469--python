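# Basal-metabolic-rate prediction coefficients (weight + height form).
# BMR (MJ/day) = weight_coef * weight_kg + height_coef * height_m + intercept,
# keyed by sex and age band [age_low, age_high).  Converted to kcal/day at
# 239.006 kcal/MJ by the caller.
- {sex: male, age_low: 0, age_high: 3, weight_coef: 0.0007, height_coef: 6.349, intercept: -2.584}
- {sex: male, age_low: 3, age_high: 10, weight_coef: 0.082, height_coef: 0.545, intercept: 1.736}
- {sex: male, age_low: 10, age_high: 18, weight_coef: 0.068, height_coef: 0.574, intercept: 2.157}
- {sex: male, age_low: 18, age_high: 30, weight_coef: 0.063, height_coef: -0.042, intercept: 2.953}
- {sex: male, age_low: 30, age_high: 60, weight_coef: 0.048, height_coef: -0.011, intercept: 3.670}
- {sex: male, age_low: 60, age_high: .inf, weight_coef: 0.038, height_coef: 4.068, intercept: -3.491}
- {sex: female, age_low: 0, age_high: 3, weight_coef: 0.068, height_coef: 4.281, intercept: -1.730}
- {sex: female, age_low: 3, age_high: 10, weight_coef: 0.071, height_coef: 0.677, intercept: 1.553}
- {sex: female, age_low: 10, age_high: 18, weight_coef: 0.035, height_coef: 1.948, intercept: 0.837}
- {sex: female, age_low: 18, age_high: 30, weight_coef: 0.057, height_coef: 1.184, intercept: 0.411}
- {sex: female, age_low: 30, age_high: 60, weight_coef: 0.034, height_coef: 0.006, intercept: 3.530}
- {sex: female, age_low: 60, age_high: .inf, weight_coef: 0.033, height_coef: 1.917, intercept: 0.074}
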