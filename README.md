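# ivsurv

Instrumental-variable survival analysis of surgical treatment effects in
region-structured registry cohorts.

## The problem

Whether resecting both the primary tumor and metastases (PMTR) prolongs
survival in stage IV colorectal cancer cannot be read off registry data
with an ordinary multivariable Cox model: surgeons select fitter patients
for aggressive surgery, and the registry never records the severity
markers that drove the choice. `ivsurv` implements the
**two-stage residual inclusion (2SRI)** instrumental-variable estimator
for this setting, using regional practice variation as the instrument: a
patient's health service area (HSA) strongly predicts what treatment they
receive — for reasons of local practice style rather than patient
severity — so a region's treatment rate identifies the treatment effect
even in the presence of unmeasured confounding.

Stage 1 fits, within race × other-treatment-rate strata, a logistic model

    logit P(T_i = 1) = a_s + b_s · Z_i,

where `Z_i` indicates the (merged) region's treatment rate at or above the
median, and forms the residual `R_i = T_i − p̂_i`. Stage 2 is a stratified
Cox model of overall survival,

    h_i(t) = h_0s(t) · w_i · exp(β T_i + γ R_i),

with a per-patient gamma frailty `w_i` (mean 1, variance θ estimated by
profile marginal likelihood). `exp(β)` is the IV hazard ratio for the
marginal population; the Wald test of `γ = 0` is the Durbin–Wu–Hausman
endogeneity test; the partial F for adding `Z` to a stratum-fixed-effects
linear-probability first stage (conventional cutoff 10) certifies
instrument strength.

The package contains the complete chain — eligibility filtering with an
exclusion tally, tumor-sidedness classification, merging of undersized
regions, instrument construction and diagnostics, a self-contained
survival engine (Kaplan–Meier with median CIs, stratified Cox with
Efron/Breslow ties, gamma-frailty Cox), naive and IV analyses per
sidedness subgroup, interaction tests, and a synthetic registry generator
that makes every stage verifiable by parameter recovery. See
`docs/methods.md` for the modelling details and caveats.

## Worked example

`examples/05_full_study.py` generates a ~10,000-patient synthetic registry
in which PMTR truly benefits left-sided disease (HR 0.37), does nothing on
the right, and an unmeasured confounder biases naive comparisons:

```
eligible patients: 9573

pmtr_vs_other:left
  IV    HR 0.38 [0.25, 0.58]  p=0.000   (F=210, DWH p=0.081)
  naive HR 0.59 [0.54, 0.65]
  median OS 31 vs 16 months (n = 555 vs 4963)

pmtr_vs_other:right
  IV    HR 1.13 [0.76, 1.68]  p=0.538   (F=245, DWH p=0.502)
  naive HR 1.30 [1.17, 1.43]
  median OS 11 vs 17 months (n = 444 vs 3611)

interaction p (PMTR effect, left vs right): 0.0007
cross-side PMTR-rate correlation r = 0.91 over 30 regions
```

The IV analysis recovers the simulated left-sided benefit (0.38 vs truth
0.37) where the naive model is biased toward the null (0.59), leaves the
right-sided null alone, and the interaction test flags the
sidedness-dependent effect. First-stage F statistics in the hundreds mark
a strong instrument. The other examples walk through each capability:
generation (`01`), filtering (`02`), instrument diagnostics (`03`) and the
survival engine (`04`).

A thin CLI mirrors the library:

```bash
ivsurv simulate --scenario sided_benefit --seed 1 --out run/
ivsurv filter --input run/cohort.csv --out run/
ivsurv analyze --input run/cohort.csv --truth run/truth.json \
       --comparison pmtr_vs_other --subgroup left --out run/left.json
```

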