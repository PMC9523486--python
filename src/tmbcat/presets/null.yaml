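# No TMB effect on either endpoint; realistic patient-level heterogeneity
# retained (responders tend to live longer: gamma < 0 on the log-hazard).
n: 100
tmb_median: 8.0
tmb_sigma: 0.6
beta0: -0.85          # ~30% objective response rate
effect_R: {kind: constant, value: 0.0}
effect_T: {kind: constant, value: 0.0}
re_structure: shared
sigma_u: 1.0
gamma: -0.8
baseline_dist: exponential
baseline_rate: 0.115  # median event time ~6 months
censor_rate: 0.04
admin_censor: 36.0
sigma_e: 0.0
scenario: "null"
true_cuts: []
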