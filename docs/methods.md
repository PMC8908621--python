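# Methods

## The problem

In population-based cancer registries, patients who undergo aggressive
surgery differ systematically from those who do not — in performance
status, tumor burden and other severity markers the registry never
records. A multivariable Cox model adjusted only for measured covariates
therefore confounds treatment benefit with patient selection. This package
implements an instrumental-variable analysis of overall survival that uses
*regional practice variation* as the instrument: the treatment rate of a
patient's health service area (HSA) predicts their own treatment, but —
under the IV assumptions — affects their survival only through that
treatment, not through their individual severity.

The estimator is **two-stage residual inclusion (2SRI)**. Stage one fits a
stratified logistic model of the treatment indicator on the dichotomized
regional rate ("below median" vs "equal to or above the median") and forms
the residual — the observed minus the predicted treatment probability.
Stage two is a stratified Cox model of survival on the treatment indicator
and that residual, with a per-patient gamma frailty term. The residual
carries the selection information (the part of treatment choice not
explained by region); the frailty term absorbs residual unmeasured
heterogeneity, which otherwise attenuates the hazard ratio (HRs are not
collapsible). The Wald test on the residual's coefficient is the
Durbin–Wu–Hausman (DWH) endogeneity test: a small p-value says treatment
is endogenous and the naive model is suspect. IV estimates apply to the
*marginal population* — patients whose treatment is swung by where they
live.

Two comparisons are built in: resection of primary plus metastases (PMTR)
versus every other strategy, and primary resection only (PTR) versus no
surgery, each run separately in left- and right-sided disease with a
pooled treatment-by-sidedness interaction test.

## Pipeline construction choices

* **Eligibility.** Site whitelist C180, C182–C189, C199, C209; histology
  whitelist 8140, 8144, 8210, 8211, 8220, 8221, 8261, 8262, 8263, 8480,
  8481; diagnosis year ≥ 2005; then the six record-level exclusions (age
  < 18, unconfirmed histology, prior malignancy, autopsy-only, missing
  follow-up, unknown surgery fields). The exclusion tally attributes each
  dropped record to the *first* failing rule in this order. Unparseable
  codes are collected as record-level validation errors and tallied, never
  silently dropped.
* **Sidedness.** Right: C180, C182, C183, C184; left: C185, C186, C187,
  C199, C209 (the anatomically complete assignment, including hepatic
  flexure on the right and descending colon on the left). C188/C189
  (overlapping / NOS) carry no side: they stay in the cohort but are
  excluded from sided subgroup analyses, explicitly.
* **Region merging.** Every HSA with fewer than 50 cases is merged into
  the region with the nearest patient-weighted centroid (Euclidean
  distance), smallest region first, recomputing after each merge; ties
  break lexicographically by region id. Counts are conserved and the final
  map is idempotent. Merging is done per sided subgroup on the subgroup's
  own cohort.
* **Instrument and strata.** Rates are computed per merged region and
  dichotomized at the unweighted interpolated median ("high" = rate ≥
  median). For PMTR-vs-other the instrument is the PMTR rate level and the
  strata are collapsed race (non-Hispanic white / non-Hispanic black /
  others, Hispanic ∈ others) × the PTR rate level; for PTR-vs-no-surgery
  the cohort is restricted to those two groups *before* instrument
  construction, the instrument is the PTR rate level within the restricted
  set, and the stratifier is the PMTR rate level computed on the full
  sided cohort (the restricted set contains no PMTR patients). The median
  split is recomputed within each sidedness subgroup.
* **First stage.** Per stratum, logit P(T=1) = a + b·Z with binary Z is
  saturated, so its exact MLE is computed in closed form from the cell
  proportions; predicted probabilities equal cell means and residuals
  center to zero within every stratum by construction. Strata with no
  treatment variation or a pure cell (complete separation) are excluded
  from both stages, with counts reported.
* **Instrument strength.** The reported F is the partial F for adding Z to
  a stratum-fixed-effects linear-probability model of T (the standard
  econometric first-stage report); the logistic likelihood-ratio statistic
  is reported alongside. F < 10 raises a weak-instrument warning but the
  analysis still runs. *Caveat:* because the median split is computed from
  in-sample rates, the F statistic has a mechanical floor that grows with
  the number of regions (the split partially chases binomial noise in the
  regional rates); with ~40 regions the floor is roughly 15–20 even when
  true practice variation is nil. Weak-instrument scenarios therefore only
  show F < 10 when regions are few or enormous.
* **Second stage.** Cox model on (treatment, residual) with
  stratum-specific baseline hazards and a per-patient gamma frailty; an
  adjusted variant (adding the naive covariates) is available behind a
  flag but off by default, since the strata and residual already carry the
  design information. Confidence intervals for the IV hazard ratio are
  model-based Wald intervals from the second stage, which ignore
  first-stage sampling noise; this is the conventional display and is
  listed under limitations.
* **Naive model.** Cox on treatment plus race (4 levels), age group, sex,
  marital status and year period, unstratified, no frailty.
* **Interaction test.** Pooled second-stage model over both subgroups with
  treatment, treatment × side, and subgroup-specific residuals; baselines
  stratified by subgroup × stratum (absorbing the side main effect); Wald
  test on the interaction coefficient.

## Survival numerics

* **Kaplan–Meier.** Product-limit with Greenwood variance; pointwise 95%
  bands on the log(−log) scale; the median and its confidence interval are
  obtained by inverting the curve and its band at 0.5
  (Brookmeyer–Crowley-style). No events ⇒ undefined median, not an error.
* **Cox.** Newton iteration on the stratified partial likelihood;
  covariance is the inverse observed information. Efron tie handling by
  default (registry follow-up in months is heavily tied), Breslow by flag.
  Convergence: relative log-likelihood change < 1e-9, at most 100
  iterations, with step-halving; non-convergence and collinearity raise
  errors carrying the iteration trace. Risk sets are evaluated by suffix
  sums over (stratum, time) groups, so each iteration is O(n p²) after one
  sort, and the sorted structure is reused across the frailty loop's many
  refits.
* **Gamma frailty.** One multiplicative frailty per patient, mean 1,
  variance θ. For fixed θ the fit is the classical EM: the E-step
  posterior mean wᵢ = (1/θ + dᵢ)/(1/θ + Λ̂ᵢ), the M-step a Cox fit with
  offsets log wᵢ and an Efron-consistent baseline. Plain EM converges
  geometrically and far too slowly for the profile likelihood to be
  trusted at practical tolerances, so cycles are SQUAREM-accelerated with
  a single Newton step per cycle (same fixed point), and β is polished by
  a full Newton solve at the end. θ is estimated by profile maximization
  of the marginal log-likelihood (gamma mixture integrated analytically)
  over a coarse grid with Brent refinement; θ = 0 reproduces the plain Cox
  fit exactly. Reported covariance conditions on the fitted frailties and
  θ (penalized-likelihood practice).
* **Identifiability caveat.** With at most one event per patient, the
  frailty variance is identified only through the bending of the marginal
  hazard ratios over time, and weakly so: θ̂ is biased toward zero at
  realistic sample sizes, and fitted-θ agreement with R's
  `survival::coxph(…, frailty(id))` was verified exactly at fixed θ.
  Discretizing follow-up to whole months (heavy ties) destroys this
  identification almost completely — the profile then prefers θ = 0 even
  when substantial heterogeneity is present, in this implementation and in
  R alike. The generator therefore emits continuous follow-up by default
  and offers `round_months=True` for tie stress-testing.

## The synthetic generator

The generator emulates exactly the structure the estimator relies on:
regions with logit-normal treatment propensities (two correlated
propensities: primary resection and metastasectomy; PMTR is their
conjunction), a standard-normal patient-level confounder U entering both
the treatment log-odds and the log hazard, measured covariates with no
survival effect by default (so the simulation truth is the single
conditional log hazard ratio of the treatment), exponential baseline
hazard, administrative censoring, optional extra gamma frailty, and a
small fraction of deliberately ineligible records to exercise filtering.
U and any frailty draw are never emitted.

Default study conditions (chosen once, as a realistic mid-size registry
scenario): 40 regions, 20% of them undersized (10–49 cases) to exercise
merging, the rest averaging ~305 patients so a cohort is ~10,000 patients;
between-region SD 0.8 on the metastasectomy logit ("strong" practice
variation; first-stage F in the hundreds); confounder effects 0.5 on both
scales (odds/hazard ratio ≈ 1.65 per SD of U — an unrecorded
performance-status-sized confounder); baseline hazard ln 2/16 per month
(untreated median 16 months, typical of stage-IV colorectal disease);
administrative censoring at 120 months; true treatment log-HR −1.0
(HR ≈ 0.37) in the benefit scenarios. Presets: `confounded_benefit`
(single-population left-sided-like benefit), `no_benefit_confounded`
(right-sided-like null), `null_effect` (no effect, no confounding —
calibration), `weak_instrument` (F below 10; few regions, see the F-floor
caveat), `frailty_on` (extra gamma frailty 0.5), `sided_benefit` (both
sides, left benefit, right null — the full-study demonstration).

What the generator does *not* emulate: real HSA geography, non-proportional
hazards, covariate-dependent censoring, metachronous metastasis, or
correlated missingness. Passing recovery tests therefore certifies the
estimator under the model's own assumptions, not registry reality.

## What the simulations show (and their sizes)

* The survival engine agrees exactly with brute-force oracles
  (product-limit over explicit risk sets; 1-D maximization of hand-coded
  Efron/Breslow partial likelihoods; lifelines; R `coxph` at fixed θ).
* Under `confounded_benefit`, the naive multivariable Cox is biased toward
  the null by roughly +0.4 on the log-HR scale, while the 2SRI estimate
  centers near the truth; the acceptance suite measures this over 200
  replicates of ~10,000 analyzed patients (mean IV log-HR ≈ −0.90 against
  the truth of −1.0, versus ≈ −0.59 naive). The residual IV bias of about
  +0.1 is the unremoved part of the non-collapsibility attenuation: with a
  randomized treatment and the same heterogeneity the marginal Cox log-HR
  is already ≈ −0.85, the profile-ML frailty variance recovers only about
  half of that gap at this sample size (θ is weakly identified from
  single-event data), and the in-sample median split contributes a small
  extra pull toward the naive estimate. The strict
  recovered-to-within-3-Monte-Carlo-SE check in the acceptance suite is
  therefore not met at this size and is reported as a known shortfall
  rather than hidden by a wider tolerance; the bias-reduction clause
  (naive bias more than twice the IV bias) holds with a wide margin.
* DWH type-I error is checked over 1000 no-confounding replicates of
  ~2,000 patients (smaller replicates keep the run within minutes; the
  test is calibration, not power). DWH *power* at these design sizes is
  governed by the IV standard error and is moderate; a directional power
  check uses strengthened confounding.
* Unit-level property tests use reduced replicate counts (30–100) chosen
  to keep the default suite fast; the acceptance suite carries the
  full-size versions.

## Known limitations

* Second-stage Wald CIs ignore first-stage noise; a region-resampling
  percentile bootstrap (`pipeline.bootstrap_iv_ci`, regions redrawn with
  replacement as the instrument's sampling units) propagates it and yields
  wider intervals. It is off by default because of its cost.
* The frailty variance is weakly identified (above); with month-rounded
  follow-up the frailty adjustment is effectively inert.
* The in-sample dichotomized instrument overstates F for many-region
  designs and contributes a small bias toward the naive estimate.
* Hazard ratios are non-collapsible: the IV estimand is conditional on
  the frailty/confounder only to the extent the frailty term captures it.
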