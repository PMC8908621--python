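"""Study orchestration: naive multivariable Cox and 2SRI instrumental-variable
analyses per comparison and sidedness subgroup, plus cross-subgroup
diagnostics and report generation.

Two comparisons are supported:

``pmtr_vs_other``
    Primary tumor resection plus metastasectomy (PMTR) versus every other
    strategy.  Instrument: the merged region's PMTR rate level; strata:
    collapsed race x the region's PTR rate level.
``ptr_vs_nosurg``
    Primary tumor resection only versus no surgery, restricted to those two
    groups *before* instrument construction.  Instrument: the region's PTR
    rate level within the restricted set; strata: collapsed race x the
    region's PMTR rate level (computed on the full sided cohort, where PMTR
    patients still exist).

The second stage is a stratified Cox model of overall survival on the
treatment indicator and the first-stage residual, with a per-patient gamma
frailty term; the Durbin–Wu–Hausman endogeneity test is the Wald test on
the residual coefficient.  A first-stage F below the conventional cutoff of
10 triggers a weak-instrument warning but the analysis still runs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (apply_eligibility_filters, merge_small_hsas,
                     sidedness_column, treatment_group_column)
from .instrument import (compute_hsa_rates, dichotomize_rate, define_strata,
                         fit_first_stage, weighted_pearson)
from .survival import (ConvergenceError, CoxFit, cox_fit, cox_frailty_fit,
                       durbin_wu_hausman, interaction_test, km_estimate)

__all__ = ["AnalysisSpec", "IVResult", "WEAK_INSTRUMENT_CUTOFF",
           "prepare_cohort", "run_naive_analysis", "run_2sri_analysis",
           "run_full_study"]

WEAK_INSTRUMENT_CUTOFF = 10.0

#: covariates of the naive multivariable model
NAIVE_COVARIATES = ("race", "age_group", "sex", "marital_status", "year_period")


@dataclass
class AnalysisSpec:
    """One analysis cell: comparison x sidedness subgroup."""

    comparison: str = "pmtr_vs_other"     # or "ptr_vs_nosurg"
    subgroup: str = "left"                # or "right"
    frailty: bool = True                  # frailty term in the second stage
    adjusted_second_stage: bool = False   # add naive covariates to stage 2
    min_region_count: int = 50

    def __post_init__(self):
        if self.comparison not in ("pmtr_vs_other", "ptr_vs_nosurg"):
            raise ValueError(f"unknown comparison {self.comparison!r}")
        if self.subgroup not in ("left", "right"):
            raise ValueError(f"unknown subgroup {self.subgroup!r}")


@dataclass
class IVResult:
    """Results of one comparison within one sidedness subgroup."""

    subgroup: str
    comparison: str
    # instrumental-variable (2SRI) estimates
    hr: float
    ci_low: float
    ci_high: float
    p: float
    log_hr: float
    se_log_hr: float
    # naive multivariable Cox
    naive_hr: float
    naive_ci: tuple[float, float]
    naive_p: float
    f_statistic: float
    weak_instrument: bool
    dwh_p: float
    frailty_variance: float | None
    median_os: dict            # arm -> {median, ci_low, ci_high}
    n_per_arm: dict            # arm -> count (usable analytic set)
    excluded_strata: int
    n_analyzed: int

    def to_dict(self) -> dict:
        return asdict(self)


def prepare_cohort(records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Eligibility-filter raw records and attach derived analysis columns
    (sidedness, treatment group).  Returns (cohort, exclusion tally)."""
    eligible, tally = apply_eligibility_filters(records)
    eligible = eligible.copy()
    eligible["sidedness"] = sidedness_column(eligible)
    eligible["treatment_group"] = treatment_group_column(eligible)
    eligible["year_period"] = pd.cut(
        eligible["year_dx"], bins=[2004, 2007, 2010, 2100],
        labels=["2005-2007", "2008-2010", "2011+"])
    return eligible, tally


def _treatment_indicator(df: pd.DataFrame, comparison: str) -> np.ndarray:
    if comparison == "pmtr_vs_other":
        return (df["treatment_group"] == "PMTR").to_numpy(dtype=float)
    return (df["treatment_group"] == "PTR_only").to_numpy(dtype=float)


def _analytic_subset(subgroup_df: pd.DataFrame, comparison: str) -> pd.DataFrame:
    if comparison == "ptr_vs_nosurg":
        return subgroup_df[subgroup_df["treatment_group"]
                           .isin(["PTR_only", "NoSurgery"])].copy()
    return subgroup_df


def _dummies(df: pd.DataFrame, cols) -> tuple[np.ndarray, list[str]]:
    """Reference-coded dummy matrix; empty levels dropped with a warning."""
    mats, names = [], []
    for c in cols:
        counts = df[c].value_counts()
        levels = [lv for lv in counts.index if counts[lv] > 0]
        if len(levels) < df[c].nunique(dropna=True):
            warnings.warn(f"empty levels of {c!r} dropped", stacklevel=2)
        levels = sorted(map(str, levels))
        for lv in levels[1:]:
            mats.append((df[c].astype(str) == lv).to_numpy(dtype=float))
            names.append(f"{c}[{lv}]")
    X = np.column_stack(mats) if mats else np.empty((len(df), 0))
    return X, names


def run_naive_analysis(cohort: pd.DataFrame, spec: AnalysisSpec) -> CoxFit:
    """Multivariable Cox of overall survival on treatment plus the measured
    covariates (race, age group, sex, marital status, year period) within
    the sided, comparison-restricted cohort.  No instrument, no frailty."""
    sub = cohort[cohort["sidedness"] == spec.subgroup]
    sub = _analytic_subset(sub, spec.comparison)
    tr = _treatment_indicator(sub, spec.comparison)
    Xc, names = _dummies(sub, NAIVE_COVARIATES)
    X = np.column_stack([tr, Xc])
    return cox_fit(X, sub["followup_months"].to_numpy(),
                   sub["event"].to_numpy(dtype=bool),
                   names=["treatment", *names])


def run_2sri_analysis(cohort: pd.DataFrame, region_coords: dict,
                      spec: AnalysisSpec, *, return_detail: bool = False):
    """Full two-stage residual inclusion analysis for one comparison and
    subgroup.  Deterministic given data and tolerances.

    Steps: restrict to the sided subgroup; merge undersized regions;
    construct the instrument (own-treatment regional rate level) and strata
    (race x opposite-treatment rate level); fit the saturated stratified
    logistic first stage; carry its residual into a stratified gamma-frailty
    Cox second stage; Wald-test the treatment (IV effect), the residual
    (Durbin–Wu–Hausman) and summarize per-arm Kaplan–Meier medians.
    """
    sub_all = cohort[cohort["sidedness"] == spec.subgroup].copy()
    if not len(sub_all):
        raise ValueError(f"no patients in subgroup {spec.subgroup!r}")
    hsa_map = merge_small_hsas(sub_all, region_coords,
                               min_count=spec.min_region_count)
    sub_all["hsa_id"] = sub_all["hsa_id"].map(hsa_map)

    analytic = _analytic_subset(sub_all, spec.comparison)
    treated = _treatment_indicator(analytic, spec.comparison)

    # instrument: own-treatment rate over the analytic set
    inst_rates = dichotomize_rate(compute_hsa_rates(analytic, treated))
    # stratifier: opposite-treatment rate over the full sided cohort
    if spec.comparison == "pmtr_vs_other":
        opp = (sub_all["treatment_group"] == "PTR_only").to_numpy(dtype=float)
    else:
        opp = (sub_all["treatment_group"] == "PMTR").to_numpy(dtype=float)
    strat_rates = dichotomize_rate(compute_hsa_rates(sub_all, opp))

    strata = define_strata(analytic, strat_rates["level"])
    inst_high = analytic["hsa_id"].map(inst_rates["level"]).eq("high").to_numpy()

    first = fit_first_stage(strata.to_numpy(), inst_high, treated)
    weak = first.f_statistic < WEAK_INSTRUMENT_CUTOFF
    if weak:
        warnings.warn(
            f"first-stage F = {first.f_statistic:.2f} is below the "
            f"conventional cutoff of {WEAK_INSTRUMENT_CUTOFF:g}; the IV "
            "estimate may be unreliable", stacklevel=2)

    use = first.usable
    dfu = analytic.loc[use]
    tr_u = treated[use]
    res_u = first.residual[use]
    times = dfu["followup_months"].to_numpy(dtype=float)
    events = dfu["event"].to_numpy(dtype=bool)
    strata_u = strata.to_numpy()[use]

    cols = [tr_u, res_u]
    names = ["treatment", "residual"]
    if spec.adjusted_second_stage:
        Xc, cn = _dummies(dfu, NAIVE_COVARIATES)
        cols.extend(Xc.T)
        names.extend(cn)
    X = np.column_stack(cols)
    fitter = cox_frailty_fit if spec.frailty else cox_fit
    second = fitter(X, times, events, strata=strata_u, names=names)

    dwh = durbin_wu_hausman(second)
    b, se = second.coef_named("treatment")
    ci = second.ci()[names.index("treatment")]
    p = second.wald_p[names.index("treatment")]

    km = {}
    n_arm = {}
    for arm, mask in [("treated", tr_u == 1), ("control", tr_u == 0)]:
        curve = km_estimate(times[mask], events[mask])
        km[arm] = {"median": curve.median, "ci_low": curve.median_ci[0],
                   "ci_high": curve.median_ci[1]}
        n_arm[arm] = int(mask.sum())

    naive = run_naive_analysis(cohort, spec)
    nb, _ = naive.coef_named("treatment")
    nci = naive.ci()[naive.names.index("treatment")]
    np_ = naive.wald_p[naive.names.index("treatment")]

    result = IVResult(
        subgroup=spec.subgroup, comparison=spec.comparison,
        hr=float(np.exp(b)), ci_low=float(ci[0]), ci_high=float(ci[1]),
        p=float(p), log_hr=float(b), se_log_hr=float(se),
        naive_hr=float(np.exp(nb)), naive_ci=(float(nci[0]), float(nci[1])),
        naive_p=float(np_), f_statistic=float(first.f_statistic),
        weak_instrument=bool(weak), dwh_p=float(dwh.p_value),
        frailty_variance=second.frailty_variance, median_os=km,
        n_per_arm=n_arm, excluded_strata=len(first.excluded_strata),
        n_analyzed=int(use.sum()))
    if return_detail:
        detail = {
            "first_stage": first, "second_stage": second, "dwh": dwh,
            "hsa_map": hsa_map, "instrument_rates": inst_rates,
            "stratifier_rates": strat_rates,
            "analytic_index": dfu.index, "treated": tr_u,
            "residual": res_u, "strata": strata_u,
            "times": times, "events": events,
        }
        return result, detail
    return result


def bootstrap_iv_ci(cohort: pd.DataFrame, region_coords: dict,
                    spec: AnalysisSpec, n_boot: int = 200,
                    seed: int = 0, alpha: float = 0.05
                    ) -> tuple[float, float]:
    """Nonparametric bootstrap CI for the IV hazard ratio, resampling
    *regions* with replacement.

    The model-based Wald interval from the second stage ignores first-stage
    sampling noise; resampling whole regions propagates it (regions are the
    instrument's sampling units).  Off by default because of its cost;
    returns the percentile interval on the HR scale.
    """
    rng = np.random.default_rng(seed)
    regions = cohort["hsa_id"].unique()
    by_region = {h: g for h, g in cohort.groupby("hsa_id")}
    est = []
    for b in range(n_boot):
        draw = rng.choice(regions, size=len(regions), replace=True)
        parts = []
        for j, h in enumerate(draw):
            g = by_region[h].copy()
            # resampled copies of a region count as distinct regions
            g["hsa_id"] = f"{h}__b{j}"
            parts.append(g)
        boot = pd.concat(parts, ignore_index=True)
        coords = {f"{h}__b{j}": region_coords[h] for j, h in enumerate(draw)}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = run_2sri_analysis(boot, coords, spec)
            est.append(res.log_hr)
        except (ValueError, np.linalg.LinAlgError, ConvergenceError):
            continue
    if len(est) < max(10, n_boot // 2):
        raise RuntimeError("too many failed bootstrap replicates")
    lo, hi = np.quantile(est, [alpha / 2, 1 - alpha / 2])
    return float(np.exp(lo)), float(np.exp(hi))


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------

def _arm_proportion_table(cohort: pd.DataFrame, region_levels: pd.Series
                          ) -> pd.DataFrame:
    """Share of each surgery strategy within high- and low-rate regions
    (rows sum to 1)."""
    lev = cohort["hsa_id"].map(region_levels)
    tab = pd.crosstab(lev, cohort["treatment_group"], normalize="index")
    return tab.sort_index()


def _baseline_table(cohort: pd.DataFrame, region_levels: pd.Series
                    ) -> pd.DataFrame:
    """Covariate distributions (count and %) by region instrument level."""
    lev = cohort["hsa_id"].map(region_levels).rename("region_level")
    rows = []
    for cov in ("age_group", "sex", "race", "marital_status", "year_period"):
        counts = pd.crosstab(cohort[cov].astype(str), lev)
        pct = counts / counts.sum(axis=0) * 100
        for level_val in counts.index:
            row = {"covariate": cov, "level": level_val}
            for g in counts.columns:
                row[f"n_{g}"] = int(counts.loc[level_val, g])
                row[f"pct_{g}"] = round(float(pct.loc[level_val, g]), 2)
            rows.append(row)
    return pd.DataFrame(rows)


def _cross_side_rate_correlation(cohort: pd.DataFrame, region_coords: dict,
                                 min_count: int) -> dict:
    """Correlation of regional PMTR rates for left- vs right-sided disease,
    weighted by regional patient count (regions merged on the full cohort)."""
    sided = cohort[cohort["sidedness"].isin(["left", "right"])].copy()
    hsa_map = merge_small_hsas(sided, region_coords, min_count=min_count)
    sided["hsa_id"] = sided["hsa_id"].map(hsa_map)
    pm = (sided["treatment_group"] == "PMTR").to_numpy(dtype=float)
    left = sided[sided["sidedness"] == "left"]
    right = sided[sided["sidedness"] == "right"]
    rl = compute_hsa_rates(left, pm[(sided["sidedness"] == "left").to_numpy()])
    rr = compute_hsa_rates(right, pm[(sided["sidedness"] == "right").to_numpy()])
    shared = rl.index.intersection(rr.index)
    if len(shared) < 3:
        return {"r": float("nan"), "n_regions": int(len(shared))}
    w = (rl.loc[shared, "n"] + rr.loc[shared, "n"]).to_numpy(dtype=float)
    r = weighted_pearson(rl.loc[shared, "rate"], rr.loc[shared, "rate"], w)
    return {"r": float(r), "n_regions": int(len(shared))}


def run_full_study(records: pd.DataFrame, region_coords: dict, *,
                   seed: int | None = None, outdir=None,
                   comparisons=("pmtr_vs_other", "ptr_vs_nosurg"),
                   subgroups=("left", "right"), frailty: bool = True,
                   min_region_count: int = 50) -> dict:
    """Run every comparison in every sidedness subgroup, the interaction
    tests, the cross-side rate correlation and the descriptive tables.

    Analyses are isolated: a failure in one cell is recorded under
    ``errors`` and does not abort the rest.  With ``outdir`` set, all
    artifacts plus a manifest (seed, version, tolerances, exclusions) are
    written; reruns with the same inputs are byte-identical.
    """
    cohort, tally = prepare_cohort(records)
    results: dict = {"analyses": {}, "interaction_p": {}, "errors": {},
                     "exclusion_tally": tally,
                     "n_eligible": int(len(cohort))}
    details: dict = {}

    for comparison in comparisons:
        for subgroup in subgroups:
            key = f"{comparison}:{subgroup}"
            spec = AnalysisSpec(comparison=comparison, subgroup=subgroup,
                                frailty=frailty,
                                min_region_count=min_region_count)
            try:
                res, det = run_2sri_analysis(cohort, region_coords, spec,
                                             return_detail=True)
                results["analyses"][key] = res.to_dict()
                details[key] = det
            except Exception as exc:   # noqa: BLE001 — isolation contract
                results["errors"][key] = f"{type(exc).__name__}: {exc}"

    for comparison in comparisons:
        keys = [f"{comparison}:{s}" for s in subgroups]
        if not all(k in details for k in keys) or len(subgroups) < 2:
            results["interaction_p"][comparison] = None
            results.setdefault("notices", []).append(
                f"interaction test skipped for {comparison}: needs both "
                "sidedness subgroups")
            continue
        parts = [details[k] for k in keys]
        treatment = np.concatenate([p["treated"] for p in parts])
        residual = np.concatenate([p["residual"] for p in parts])
        side = np.concatenate([np.repeat(s, len(parts[i]["treated"]))
                               for i, s in enumerate(subgroups)])
        times = np.concatenate([p["times"] for p in parts])
        events = np.concatenate([p["events"] for p in parts])
        strata = np.concatenate([p["strata"] for p in parts])
        p_int, _ = interaction_test(treatment, side, residual, times, events,
                                    strata, frailty=frailty)
        results["interaction_p"][comparison] = float(p_int)

    try:
        results["pmtr_rate_correlation"] = _cross_side_rate_correlation(
            cohort, region_coords, min_region_count)
    except Exception as exc:   # noqa: BLE001
        results["errors"]["pmtr_rate_correlation"] = f"{type(exc).__name__}: {exc}"

    tables = {}
    key = f"pmtr_vs_other:{subgroups[0]}"
    if key in details:
        lev = details[key]["instrument_rates"]["level"]
        sub = cohort[cohort["sidedness"] == subgroups[0]].copy()
        sub["hsa_id"] = sub["hsa_id"].map(details[key]["hsa_map"])
        tables["arm_proportions"] = _arm_proportion_table(sub, lev)
        tables["baseline"] = _baseline_table(sub, lev)

    if outdir is not None:
        _write_artifacts(outdir, results, details, tables, seed)
    results["tables"] = {k: v.to_dict() for k, v in tables.items()}
    return results


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _write_artifacts(outdir, results, details, tables, seed) -> None:
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "results.json", "w") as fh:
        json.dump(results, fh, indent=1, sort_keys=True, default=_json_default,
                  allow_nan=True)
    for key, det in details.items():
        tag = key.replace(":", "_")
        det["instrument_rates"].to_csv(out / f"regions_{tag}.csv")
        first = pd.DataFrame({
            "patient_id": det["analytic_index"],
            "stratum": det["strata"],
            "treated": det["treated"],
            "residual": det["residual"],
        })
        first.to_csv(out / f"first_stage_{tag}.csv", index=False)
        diag = {"first_stage": det["first_stage"].diagnostics_dict(),
                "second_stage": det["second_stage"].summary_dict(),
                "hsa_merge_map": det["hsa_map"]}
        with open(out / f"diagnostics_{tag}.json", "w") as fh:
            json.dump(diag, fh, indent=1, sort_keys=True,
                      default=_json_default)
        from .survival import km_estimate
        rows = []
        for arm in (1.0, 0.0):
            m = det["treated"] == arm
            curve = km_estimate(det["times"][m], det["events"][m])
            rows.append(pd.DataFrame({
                "arm": "treated" if arm else "control",
                "time": curve.times, "survival": curve.survival,
                "at_risk": curve.at_risk, "n_events": curve.n_events,
                "ci_lower": curve.ci_lower, "ci_upper": curve.ci_upper}))
        pd.concat(rows).to_csv(out / f"km_{tag}.csv", index=False)
    for name, tab in tables.items():
        tab.to_csv(out / f"{name}.csv")
    manifest = {
        "package": "ivsurv",
        "version": __version__,
        "seed": seed,
        "weak_instrument_cutoff": WEAK_INSTRUMENT_CUTOFF,
        "newton_rel_tol": 1e-9,
        "excluded_strata": {k: d["first_stage"].excluded_strata
                            for k, d in details.items()},
        "analyses": sorted(details.keys()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
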