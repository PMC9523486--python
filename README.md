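# tmbcat

Optimal categorization of tumor mutation burden (TMB) from joint
response/survival endpoints.

TMB (somatic mutations per megabase) is a stratification biomarker for
immune-checkpoint-inhibitor therapy, but there is no agreement on how
many cutpoints to use or where to put them: the objective-response
endpoint (CR/PR vs SD/PD) and the time-to-event endpoint (PFS/OS) can
point in different directions, they are correlated within a patient,
and TMB is measured with error.  `tmbcat` is a small toolkit for
statisticians and translational researchers that

1. fits a **joint mixed model** of both endpoints — a logistic response
   submodel and a Cox hazard submodel linked by patient-level random
   effects,
2. optionally corrects the fit for **additive TMB measurement error**
   (regression calibration or a Nakamura-type corrected score),
3. turns the fit into a per-patient **joint favorable-prognosis
   probability** `p_i = Pr(R_i = 1, T_i* > T0)`,
4. searches all candidate threshold vectors `Cut_k = (t_1 < ... < t_k)`
   for the one **minimizing the p-value** of a between-subgroup
   discrepancy statistic `D_k` (one-way-ANOVA F, Kruskal–Wallis rank,
   or an ANOSIM-style similarity statistic with permutation p-values),
   and
5. chooses the number of thresholds `k` stepwise: add a subgroup only
   while the minimal p-value keeps decreasing.

The model, in standard notation:

```
R_i | u_i   ~  Bernoulli( expit(b0 + b1·TMB_i + u_i) )
h_i(t|v_i)  =  h0(t) · exp(alpha·TMB_i + v_i)
v_i = gamma·u_i,  u_i ~ N(0, sigma_u²)        (shared-effect default)
p_i = Pr(R_i = 1, T_i* > T0)                   (joint prognosis score)
D_k = discrepancy of {p_i} across the k+1 TMB subgroups
Cut_k* = argmin p-value(D_k);  k* chosen by stepwise minimal-p descent
```

A synthetic-cohort generator with versioned scenario presets
(`consistent`, `inconsistent`, `null`) reproduces the study conditions
used throughout the tests.  See `docs/methods.md` for the estimation
details, all defaults, and known limitations.

## Worked example

Simulate a cohort in which the two endpoints disagree over a middle TMB
band (response odds rise above 7 mut/Mb, but the hazard is elevated in
the 7–14 band), then let the pipeline pick the categorization:

```python
from tmbcat import scenario_presets, simulate_cohort, run_pipeline
from tmbcat.report import PipelineConfig
from tmbcat.threshold_search import SearchConfig

cfg = scenario_presets("inconsistent")
cohort, _ = simulate_cohort(cfg, seed=11)
result = run_pipeline(
    cohort,
    PipelineConfig(search=SearchConfig(k_range=(1, 2, 3), max_candidates=20,
                                       min_group_size=15, T0=6.0, seed=17)),
)
print("k:", result.k, "thresholds:", [round(t, 2) for t in result.cuts.thresholds])
```

```
[tmbcat] fitting joint model (n=180, sigma_e=0.0)
[tmbcat] joint probabilities computed (mode=eb, T0=6)
[tmbcat] k=1: best p=1.364e-39 at (14.1943398119225,)
[tmbcat] k=2: best p=2.817e-60 at (8.8810437386182, 17.00920570863025)
[tmbcat] k=3: best p=5.591e-65 at (7.912921269707911, 11.656540385714747, 17.00920570863025)
[tmbcat] selected k=3, thresholds=(7.912921269707911, 11.656540385714747, 17.00920570863025)
k: 3 thresholds: [7.91, 11.66, 17.01]
```

The minimal-p trace falls from `1.4e-39` (one cut) to `2.8e-60` (two
cuts), so a single "TMB-high" rule is rejected; the first selected cut
(7.9 mut/Mb) lands on the planted low/middle boundary.  The subgroup
report (`result.report`) shows why: the middle groups respond more
often (ORR 43% and 62% vs 32% in TMB-low) yet progress fastest (median
PFS 0.6 and 2.5 months), while patients above ~17 mut/Mb keep both a
high ORR and a 25.1-month median PFS — exactly the
inconsistent-direction structure, which no single threshold can
express.  Searched minimal p-values are selection-optimistic and should
be read as ranking scores; the log-rank test across the chosen groups
(chi² = 52.2, p = 2.7e-11) is the conventional companion summary.  With
model-estimated probabilities the stepwise rule tends to split one
group more than was planted (here 3 cuts rather than 2, subdividing the
high band); `docs/methods.md` discusses this behavior.

The same pipeline is available from the shell:

```sh
tmbcat simulate --preset inconsistent --n 180 --seed 11 --out cohort.csv
tmbcat search --input cohort.csv --method anova --k-max 3 --t0 6 \
              --min-group 15 --seed 17 --out results/
```

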