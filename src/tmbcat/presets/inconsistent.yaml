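# The two endpoints disagree over a middle TMB band (7-14 mut/Mb):
# response odds rise from 7 upward, but the hazard is elevated in the
# middle band and reduced only above 14, so two thresholds (k = 2)
# separating low / middle / high are optimal.
n: 180
tmb_median: 8.0
tmb_sigma: 0.6
beta0: -1.4
effect_R: {kind: step, breaks: [7.0], values: [0.0, 1.5]}
effect_T: {kind: step, breaks: [7.0, 14.0], values: [0.0, 1.6, -0.8]}
re_structure: shared
sigma_u: 0.8
gamma: -0.8
baseline_dist: exponential
baseline_rate: 0.115
censor_rate: 0.04
admin_censor: 36.0
sigma_e: 0.0
scenario: inconsistent
true_cuts: [7.0, 14.0]
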