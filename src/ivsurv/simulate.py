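"""Synthetic registry-cohort generator.

Emulates the statistical structure a regional-instrument analysis relies
on, without any real registry extract:

* regions (health service areas) with practice-style variation in surgical
  propensity — the instrument;
* a patient-level unmeasured confounder U ~ N(0,1) that raises both the
  odds of surgery and the death hazard, and is *not* emitted in the
  records;
* measured covariates (age, sex, race, marital status, year, site code)
  with zero survival effect by default, so the simulation truth is a single
  log hazard ratio per treatment;
* exponential proportional-hazards survival with administrative censoring,
  optionally with extra gamma frailty.

Surgery is modelled through two indicators: resection of the primary
(``surgery_primary``) and of metastases (``surgery_mets``), each with its
own region-level log-odds propensity; PMTR (primary resection plus
metastasectomy) is their conjunction.  Region propensities for the two
indicators are correlated across regions, mimicking the observation that
areas favouring one operation tend to favour the other, and each sidedness
subgroup receives a small independent jitter so the left/right rate
correlation across regions is strong but below 1.

Follow-up is continuous months: exponential death times truncated by
administrative censoring, per the generator's proportional-hazards
contract.  ``round_months=True`` coarsens follow-up to whole months, the
registry convention, producing heavily tied data for stress-testing tie
handling.  (Discretization weakens the identifiability of individual
frailty variance, so it is off by default; see the methods note.)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .cohort import (AGE_GROUP_LABELS, LEFT_SITES, RIGHT_SITES,
                     derive_age_group)

__all__ = ["SimulationConfig", "SimulationTruth", "generate_regions",
           "generate_cohort", "scenario_library", "SCENARIOS"]

_LEFT_CODES = sorted(LEFT_SITES)
_RIGHT_CODES = sorted(RIGHT_SITES)
_HISTOLOGIES = (8140, 8480, 8481, 8210, 8261, 8263)
_RACES = ("non-Hispanic white", "non-Hispanic black", "Hispanic", "other")
_RACE_P = (0.65, 0.12, 0.15, 0.08)
_MARITAL = ("married", "widowed", "other")
_MARITAL_P = (0.52, 0.13, 0.35)


@dataclass
class SimulationConfig:
    """Generator parameters.

    The defaults describe a mid-size registry scenario: 40 regions of mean
    size 250 (total n ~ 10,000), strong regional practice variation
    (logit-scale SD 0.8 of the metastasectomy propensity), a moderate
    unmeasured confounder (odds ratio and hazard ratio e^0.5 ~ 1.65 per SD
    of U, the scale of an unrecorded performance-status difference), an
    untreated median survival of 16 months (exponential rate ln 2 / 16 per
    month) and administrative censoring at 120 months.
    """

    seed: int
    n_regions: int = 40
    region_size_mean: float = 305.0   # with the small-region share: n ~ 10,000
    region_size_dispersion: float = 0.3   # gamma-Poisson CV of large regions
    small_region_fraction: float = 0.2    # regions drawn undersized (< 50)
    pmtr_logit_mean: float = -1.9         # metastasectomy propensity (logit)
    ptr_logit_mean: float = 0.3           # primary-resection propensity (logit)
    instrument_sd: float = 0.8            # between-region SD, mets logit
    ptr_instrument_sd: float = 0.5        # between-region SD, primary logit
    propensity_corr: float = 0.5          # corr of the two region propensities
    side_jitter_sd: float = 0.25          # per-side extra region noise
    confounder_effect_treatment: float = 0.5   # log-odds per unit U
    confounder_effect_hazard: float = 0.5      # log-hazard per unit U
    true_log_hr_pmtr: float = -1.0
    true_log_hr_ptr: float = 0.0
    true_log_hr_mtr: float = 0.0
    true_log_hr_pmtr_right: float | None = None   # None -> same as left
    true_log_hr_ptr_right: float | None = None
    baseline_hazard: float = float(np.log(2) / 16)  # per month
    admin_censor_months: float = 120.0
    frailty_variance: float = 0.0
    age_log_hr_per_decade: float = 0.0
    male_log_hr: float = 0.0
    prop_left: float = 0.58
    ineligible_fraction: float = 0.02     # records violating eligibility rules
    round_months: bool = False

    def validate(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least two regions")
        if self.region_size_mean <= 1:
            raise ValueError("degenerate region size distribution")
        if self.admin_censor_months <= 0:
            raise ValueError("administrative censoring horizon must be "
                             "positive, otherwise the event rate is zero")
        if self.frailty_variance < 0:
            raise ValueError("frailty variance must be nonnegative")
        if not 0 <= self.small_region_fraction < 1:
            raise ValueError("small_region_fraction must be in [0, 1)")


@dataclass
class SimulationTruth:
    """Echo of the configuration plus realized per-region propensities —
    sufficient to compute true quantities for parameter-recovery tests."""

    config: dict
    regions: dict            # hsa_id -> {size, x, y, logit_primary, logit_mets}
    n_patients: int
    event_fraction: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def _spawn(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_regions(config: SimulationConfig) -> pd.DataFrame:
    """Draw regions: sizes, planar coordinates and treatment propensities.

    A configurable fraction of regions is undersized (10–49 cases) to
    exercise the merging rule; the rest follow a gamma-Poisson around
    ``region_size_mean``.  The two surgery propensities are bivariate
    normal on the logit scale with correlation ``propensity_corr``.
    """
    config.validate()
    rng, = _spawn(config.seed, 1)
    k = config.n_regions
    small = rng.random(k) < config.small_region_fraction
    shape = 1.0 / config.region_size_dispersion ** 2
    lam = config.region_size_mean * rng.gamma(shape, 1.0 / shape, size=k)
    sizes = np.where(small,
                     rng.integers(10, 50, size=k),
                     np.maximum(1, rng.poisson(lam)))
    xy = rng.random((k, 2))
    z = rng.multivariate_normal(
        [0.0, 0.0],
        [[1.0, config.propensity_corr], [config.propensity_corr, 1.0]], size=k)
    logit_mets = config.pmtr_logit_mean + config.instrument_sd * z[:, 0]
    logit_primary = config.ptr_logit_mean + config.ptr_instrument_sd * z[:, 1]
    ids = [f"HSA{i:03d}" for i in range(k)]
    return pd.DataFrame({"hsa_id": ids, "size": sizes.astype(int),
                         "x": xy[:, 0], "y": xy[:, 1],
                         "logit_primary": logit_primary,
                         "logit_mets": logit_mets}).set_index("hsa_id")


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(config: SimulationConfig
                    ) -> tuple[pd.DataFrame, SimulationTruth]:
    """Generate the per-patient case listing and the simulation truth.

    The unmeasured confounder U and any frailty draw never appear in the
    emitted records.  The returned frame uses the cohort module's column
    dictionary and can be written/read as CSV unchanged.
    """
    config.validate()
    regions = generate_regions(config)
    rng_cov, rng_treat, rng_surv, rng_noise = _spawn(config.seed + 1, 4)

    reg_idx = np.repeat(np.arange(len(regions)), regions["size"].values)
    n = reg_idx.size
    hsa = regions.index.values[reg_idx]

    # measured covariates (no survival effect unless configured)
    age = np.clip(rng_cov.normal(66, 13, n).round(), 20, 99).astype(int)
    sex = rng_cov.choice(["male", "female"], size=n)
    race = rng_cov.choice(_RACES, size=n, p=_RACE_P)
    marital = rng_cov.choice(_MARITAL, size=n, p=_MARITAL_P)
    year = rng_cov.integers(2005, 2016, size=n)
    left = rng_cov.random(n) < config.prop_left
    site = np.where(left,
                    rng_cov.choice(_LEFT_CODES, size=n),
                    rng_cov.choice(_RIGHT_CODES, size=n))
    histology = rng_cov.choice(_HISTOLOGIES, size=n)

    # treatment: two surgery indicators with region propensity + confounder
    U = rng_treat.normal(size=n)
    side_jit_m = rng_treat.normal(0, config.side_jitter_sd, (len(regions), 2))
    side_jit_p = rng_treat.normal(0, config.side_jitter_sd, (len(regions), 2))
    side_col = (~left).astype(int)  # 0 = left, 1 = right
    lp_mets = (regions["logit_mets"].values[reg_idx]
               + side_jit_m[reg_idx, side_col]
               + config.confounder_effect_treatment * U)
    lp_prim = (regions["logit_primary"].values[reg_idx]
               + side_jit_p[reg_idx, side_col]
               + config.confounder_effect_treatment * U)
    s_mets = rng_treat.random(n) < _expit(lp_mets)
    s_prim = rng_treat.random(n) < _expit(lp_prim)
    pmtr = s_prim & s_mets
    ptr_only = s_prim & ~s_mets
    mtr_only = ~s_prim & s_mets

    # survival: exponential PH with confounder, covariates and frailty
    b_pmtr = np.where(left, config.true_log_hr_pmtr,
                      config.true_log_hr_pmtr
                      if config.true_log_hr_pmtr_right is None
                      else config.true_log_hr_pmtr_right)
    b_ptr = np.where(left, config.true_log_hr_ptr,
                     config.true_log_hr_ptr
                     if config.true_log_hr_ptr_right is None
                     else config.true_log_hr_ptr_right)
    log_hazard = (np.log(config.baseline_hazard)
                  + b_pmtr * pmtr + b_ptr * ptr_only
                  + config.true_log_hr_mtr * mtr_only
                  + config.confounder_effect_hazard * U
                  + config.age_log_hr_per_decade * (age - 66) / 10.0
                  + config.male_log_hr * (sex == "male"))
    if config.frailty_variance > 0:
        th = config.frailty_variance
        log_hazard = log_hazard + np.log(rng_surv.gamma(1 / th, th, n))
    t_death = rng_surv.exponential(np.exp(-log_hazard))
    c = config.admin_censor_months
    event = t_death <= c
    followup = np.minimum(t_death, c)
    if config.round_months:
        followup = np.minimum(np.ceil(followup), c)
    if not event.any():
        raise ValueError("configuration implies an event rate of zero")

    df = pd.DataFrame({
        "patient_id": [f"P{i:07d}" for i in range(n)],
        "age": age,
        "age_group": derive_age_group(age),
        "sex": sex,
        "race": race,
        "marital_status": marital,
        "year_dx": year,
        "hsa_id": hsa,
        "site_code": site,
        "histology_code": histology,
        "histology_confirmed": True,
        "prior_malignancy": False,
        "autopsy_only": False,
        "surgery_primary": np.where(s_prim, "yes", "no"),
        "surgery_mets": np.where(s_mets, "yes", "no"),
        "followup_months": followup,
        "event": event,
        "tumor_size": rng_cov.choice(["<4cm", ">=4cm", "unknown"], size=n,
                                     p=(0.35, 0.45, 0.2)),
        "grade": rng_cov.choice(["1-2", "3-4", "unknown"], size=n,
                                p=(0.6, 0.25, 0.15)),
        "t_stage": rng_cov.choice(["T1-2", "T3-4", "unknown"], size=n,
                                  p=(0.12, 0.68, 0.2)),
        "n_stage": rng_cov.choice(["N0", "N1-2", "unknown"], size=n,
                                  p=(0.3, 0.58, 0.12)),
    })
    _inject_ineligible(df, config, rng_noise)

    truth = SimulationTruth(
        config=asdict(config),
        regions={h: {"size": int(r["size"]), "x": float(r["x"]),
                     "y": float(r["y"]),
                     "logit_primary": float(r["logit_primary"]),
                     "logit_mets": float(r["logit_mets"])}
                 for h, r in regions.iterrows()},
        n_patients=int(n),
        event_fraction=float(event.mean()),
    )
    return df, truth


def _inject_ineligible(df: pd.DataFrame, config: SimulationConfig, rng) -> None:
    """Overwrite a small fraction of records with eligibility violations so
    the filtering stage has work to do; violations cycle through the rules."""
    n_bad = int(round(config.ineligible_fraction * len(df)))
    if n_bad == 0:
        return
    idx = rng.choice(len(df), size=n_bad, replace=False)
    kinds = np.arange(n_bad) % 7
    col = {c: df.columns.get_loc(c) for c in
           ["age", "histology_confirmed", "prior_malignancy", "autopsy_only",
            "followup_months", "surgery_primary", "year_dx", "site_code"]}
    for i, kind in zip(idx, kinds):
        if kind == 0:
            df.iat[i, col["age"]] = int(rng.integers(10, 18))
        elif kind == 1:
            df.iat[i, col["histology_confirmed"]] = False
        elif kind == 2:
            df.iat[i, col["prior_malignancy"]] = True
        elif kind == 3:
            df.iat[i, col["autopsy_only"]] = True
        elif kind == 4:
            df.iat[i, col["followup_months"]] = np.nan
        elif kind == 5:
            df.iat[i, col["surgery_primary"]] = "unknown"
        else:
            df.iat[i, col["year_dx"]] = int(rng.integers(1998, 2005))


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------

def _confounded_benefit(seed):
    """Left-sided-like benefit under confounding: a single-population cohort
    (all left-sided) with true log-HR −1.0 (HR 0.37), a confounder raising
    both treatment odds and hazard, and a strong instrument.  Drives the
    headline property: naive Cox is biased toward the null while 2SRI
    recovers the truth."""
    return SimulationConfig(seed=seed, prop_left=1.0)


def _no_benefit_confounded(seed):
    """Right-sided-like null effect with the same confounding: naive Cox
    shows a spurious association, the IV hazard ratio stays near 1."""
    return SimulationConfig(seed=seed, prop_left=0.0, true_log_hr_pmtr=0.0,
                            true_log_hr_pmtr_right=0.0)


def _null_effect(seed):
    """No treatment effect, no confounding: calibration scenario.  The
    endogeneity (DWH) test should reject at its nominal level and treated /
    untreated survival curves are indistinguishable."""
    return SimulationConfig(seed=seed, true_log_hr_pmtr=0.0,
                            true_log_hr_ptr=0.0, true_log_hr_mtr=0.0,
                            confounder_effect_treatment=0.0,
                            confounder_effect_hazard=0.0)


def _weak_instrument(seed):
    """Negligible between-region practice variation: the first-stage F drops
    below the conventional cutoff of 10 and a warning is recorded.  Few
    regions are used because a median split computed on in-sample rates has
    a mechanical F floor that grows with the number of regions (the split
    chases binomial noise in the regional rates; see the methods note)."""
    return SimulationConfig(seed=seed, instrument_sd=0.03,
                            ptr_instrument_sd=0.03, side_jitter_sd=0.0,
                            n_regions=8, small_region_fraction=0.0,
                            prop_left=1.0)


def _frailty_on(seed):
    """Extra gamma frailty (variance 0.5) on top of the default scenario,
    for frailty-recovery and robustness checks."""
    return SimulationConfig(seed=seed, frailty_variance=0.5)


def _sided_benefit(seed):
    """Full-study analogue: benefit for left-sided disease (log-HR −1.0),
    none for right-sided; primary-resection-only effect null on both sides;
    confounding on.  Used for end-to-end demonstrations."""
    return SimulationConfig(seed=seed, true_log_hr_pmtr=-1.0,
                            true_log_hr_pmtr_right=0.0)


SCENARIOS = {
    "confounded_benefit": _confounded_benefit,
    "no_benefit_confounded": _no_benefit_confounded,
    "null_effect": _null_effect,
    "weak_instrument": _weak_instrument,
    "frailty_on": _frailty_on,
    "sided_benefit": _sided_benefit,
}


def scenario_library(name: str, seed: int, **overrides) -> SimulationConfig:
    """Named preset configurations; ``overrides`` replace individual fields
    (e.g. a smaller ``n_regions`` for quick runs)."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; available: "
                       f"{sorted(SCENARIOS)}")
    cfg = SCENARIOS[name](seed)
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise AttributeError(f"SimulationConfig has no field {k!r}")
        setattr(cfg, k, v)
    return cfg
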