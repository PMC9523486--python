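# Both endpoints improve above one planted cutpoint (TMB >= 10 mut/Mb):
# response odds rise and hazard falls together, so a single threshold
# (k = 1) is optimal.
n: 150
tmb_median: 8.0
tmb_sigma: 0.6
beta0: -1.4
effect_R: {kind: step, breaks: [10.0], values: [0.0, 1.8]}
effect_T: {kind: step, breaks: [10.0], values: [0.0, -1.2]}
re_structure: shared
sigma_u: 0.8
gamma: -0.8
baseline_dist: exponential
baseline_rate: 0.115
censor_rate: 0.04
admin_censor: 36.0
sigma_e: 0.0
scenario: consistent
true_cuts: [10.0]
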