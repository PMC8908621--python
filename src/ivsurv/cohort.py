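"""Cohort construction: parsing, eligibility filtering, sidedness, treatment
groups and merging of undersized health service areas (HSAs).

The cohort is carried as a pandas DataFrame, one row per patient, with the
column dictionary below (the same schema the synthetic generator writes):

======================  =====================================================
column                  meaning
======================  =====================================================
patient_id              opaque identifier (string)
age                     age at diagnosis, years (integer)
age_group               derived ordered category: <50, 50-59, 60-69, 70-79, >=80
sex                     "male" / "female"
race                    "non-Hispanic white" / "non-Hispanic black" /
                        "Hispanic" / "other"
marital_status          "married" / "widowed" / "other"
year_dx                 calendar year of diagnosis
hsa_id                  health service area identifier (string)
site_code               ICD-O-3 topography, e.g. "C180"
histology_code          ICD-O-3 morphology (integer)
histology_confirmed     boolean
prior_malignancy        boolean
autopsy_only            boolean
surgery_primary         "yes" / "no" / "unknown"  (never silently coerced)
surgery_mets            "yes" / "no" / "unknown"
followup_months         nonnegative; may be missing before filtering
event                   boolean, death from any cause
tumor_size, grade,      categories, each with an explicit "unknown" level
t_stage, n_stage
======================  =====================================================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SITE_WHITELIST", "RIGHT_SITES", "LEFT_SITES", "UNASSIGNED_SITES",
    "HISTOLOGY_WHITELIST", "AGE_GROUP_EDGES", "ELIGIBILITY_RULES",
    "CohortValidationError", "load_cohort", "validate_cohort",
    "apply_eligibility_filters", "classify_sidedness", "sidedness_column",
    "assign_treatment_group", "treatment_group_column", "merge_small_hsas",
    "derive_age_group",
]

# ICD-O-3 topography: colorectal sites analyzed (C181 = appendix excluded)
SITE_WHITELIST = frozenset(
    ["C180", "C182", "C183", "C184", "C185", "C186", "C187", "C188", "C189",
     "C199", "C209"])
# cecum, ascending colon, hepatic flexure, transverse colon
RIGHT_SITES = frozenset(["C180", "C182", "C183", "C184"])
# splenic flexure, descending colon, sigmoid, rectosigmoid junction, rectum
LEFT_SITES = frozenset(["C185", "C186", "C187", "C199", "C209"])
# overlapping lesion / colon NOS: in the included range but in neither sided
# list; kept in the cohort, excluded from sided subgroup analyses
UNASSIGNED_SITES = frozenset(["C188", "C189"])

# adenocarcinoma morphologies
HISTOLOGY_WHITELIST = frozenset(
    [8140, 8144, 8210, 8211, 8220, 8221, 8261, 8262, 8263, 8480, 8481])

MIN_YEAR_DX = 2005

AGE_GROUP_EDGES = (50, 60, 70, 80)
AGE_GROUP_LABELS = ("<50", "50-59", "60-69", "70-79", ">=80")

REQUIRED_COLUMNS = [
    "patient_id", "age", "sex", "race", "marital_status", "year_dx",
    "hsa_id", "site_code", "histology_code", "histology_confirmed",
    "prior_malignancy", "autopsy_only", "surgery_primary", "surgery_mets",
    "followup_months", "event",
]
OPTIONAL_COLUMNS = ["age_group", "tumor_size", "grade", "t_stage", "n_stage"]

_BOOL_COLS = ["histology_confirmed", "prior_malignancy", "autopsy_only", "event"]
_TRISTATE = frozenset(["yes", "no", "unknown"])


class CohortValidationError(ValueError):
    """Schema or record-level validation failure; carries per-row messages."""

    def __init__(self, message: str, errors: list[str] | None = None):
        super().__init__(message)
        self.errors = errors or []


def derive_age_group(age) -> pd.Categorical:
    """Bin age in years into the five analysis groups."""
    bins = [-np.inf, *AGE_GROUP_EDGES, np.inf]
    return pd.cut(np.asarray(age, dtype=float), bins=bins,
                  labels=AGE_GROUP_LABELS, right=False)


def validate_cohort(df: pd.DataFrame) -> list[str]:
    """Collect record-level validation errors (unparseable codes etc.).

    Returns a list of messages; an empty list means the frame is clean.
    Unparseable codes are reported, never silently dropped — callers decide
    (``apply_eligibility_filters`` tallies them under ``unparseable_code``).
    """
    errors: list[str] = []
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing required columns: {missing}")
    site = df["site_code"].astype(str)
    bad_site = ~site.str.fullmatch(r"C\d{3}")
    for pid in df.loc[bad_site, "patient_id"]:
        errors.append(f"patient {pid}: unparseable site code")
    hist = pd.to_numeric(df["histology_code"], errors="coerce")
    for pid in df.loc[hist.isna(), "patient_id"]:
        errors.append(f"patient {pid}: unparseable histology code")
    bad_tri = ~df["surgery_primary"].isin(_TRISTATE) \
        | ~df["surgery_mets"].isin(_TRISTATE)
    for pid in df.loc[bad_tri, "patient_id"]:
        errors.append(f"patient {pid}: surgery field outside yes/no/unknown")
    neg_fu = df["followup_months"].notna() & (df["followup_months"] < 0)
    for pid in df.loc[neg_fu, "patient_id"]:
        errors.append(f"patient {pid}: negative follow-up")
    return errors


def load_cohort(path) -> pd.DataFrame:
    """Read a delimited case listing (CSV/TSV by extension; UTF-8, header
    required) and normalize dtypes.  Raises CohortValidationError on schema
    problems; record-level code errors are left for the eligibility filter
    to tally."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"patient_id": str, "hsa_id": str,
                                           "site_code": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing required columns: {missing}")
    for c in _BOOL_COLS:
        if df[c].dtype == object:
            df[c] = df[c].map({"True": True, "False": False,
                               True: True, False: False})
        df[c] = df[c].astype(bool)
    df["followup_months"] = pd.to_numeric(df["followup_months"], errors="coerce")
    if "age_group" not in df.columns:
        df["age_group"] = derive_age_group(df["age"])
    return df


# ---------------------------------------------------------------------------
# Eligibility
# ---------------------------------------------------------------------------

def _r_unparseable(df):
    site_ok = df["site_code"].astype(str).str.fullmatch(r"C\d{3}")
    hist_ok = pd.to_numeric(df["histology_code"], errors="coerce").notna()
    return ~(site_ok & hist_ok)


def _r_site(df):
    return ~df["site_code"].isin(SITE_WHITELIST)


def _r_histology(df):
    hist = pd.to_numeric(df["histology_code"], errors="coerce")
    return ~hist.isin(HISTOLOGY_WHITELIST)


def _r_year(df):
    return df["year_dx"] < MIN_YEAR_DX


def _r_age(df):
    return df["age"] < 18


def _r_not_confirmed(df):
    return ~df["histology_confirmed"].astype(bool)


def _r_prior_malignancy(df):
    return df["prior_malignancy"].astype(bool)


def _r_autopsy_only(df):
    return df["autopsy_only"].astype(bool)


def _r_followup(df):
    return df["followup_months"].isna()


def _r_surgery_unknown(df):
    return (df["surgery_primary"] == "unknown") | (df["surgery_mets"] == "unknown")


#: Ordered eligibility rules.  Whitelists come first, then the six numbered
#: exclusions in their published order; the tally attributes each excluded
#: record to the first failing rule in this order.
ELIGIBILITY_RULES: list[tuple[str, callable]] = [
    ("unparseable_code", _r_unparseable),
    ("site_not_colorectal", _r_site),
    ("histology_not_adenocarcinoma", _r_histology),
    ("year_before_2005", _r_year),
    ("age_under_18", _r_age),
    ("not_histologically_confirmed", _r_not_confirmed),
    ("prior_malignancy", _r_prior_malignancy),
    ("autopsy_only", _r_autopsy_only),
    ("incomplete_followup", _r_followup),
    ("surgery_info_incomplete", _r_surgery_unknown),
]


def apply_eligibility_filters(df: pd.DataFrame, rules=None
                              ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the eligibility rules; return (eligible frame, exclusion tally).

    Every retained record passes all rules.  Each excluded record is counted
    exactly once, under the first rule it fails in the declared order, so
    ``len(eligible) + sum(tally.values()) == len(df)``.  The operation is
    idempotent: filtering its own output changes nothing.
    """
    if rules is None:
        rules = ELIGIBILITY_RULES
    remaining = np.ones(len(df), dtype=bool)
    tally: dict[str, int] = {}
    for name, rule in rules:
        fails = np.asarray(rule(df), dtype=bool) & remaining
        tally[name] = int(fails.sum())
        remaining &= ~fails
    eligible = df.loc[remaining].copy()
    eligible["age_group"] = derive_age_group(eligible["age"])
    return eligible, tally


# ---------------------------------------------------------------------------
# Sidedness and treatment groups
# ---------------------------------------------------------------------------

def classify_sidedness(site_code: str) -> str:
    """Tumor sidedness from the ICD-O-3 topography code.

    Right: cecum (C180), ascending colon (C182), hepatic flexure (C183),
    transverse colon (C184).  Left: splenic flexure (C185), descending colon
    (C186), sigmoid (C187), rectosigmoid junction (C199), rectum (C209).
    Overlapping lesion (C188) and colon NOS (C189) carry no side and return
    "unassigned"; such records are excluded from sided subgroup analyses.
    """
    if site_code in RIGHT_SITES:
        return "right"
    if site_code in LEFT_SITES:
        return "left"
    if site_code in UNASSIGNED_SITES:
        return "unassigned"
    raise ValueError(f"site code {site_code!r} is outside the analyzed "
                     "colorectal whitelist")


def sidedness_column(df: pd.DataFrame) -> pd.Series:
    """Vectorized sidedness for an eligible cohort."""
    out = pd.Series("unassigned", index=df.index, dtype=object)
    out[df["site_code"].isin(RIGHT_SITES)] = "right"
    out[df["site_code"].isin(LEFT_SITES)] = "left"
    bad = ~df["site_code"].isin(SITE_WHITELIST)
    if bad.any():
        codes = sorted(df.loc[bad, "site_code"].unique())
        raise ValueError(f"site codes outside the whitelist: {codes}")
    return out


def assign_treatment_group(surgery_primary: str, surgery_mets: str) -> str:
    """Four-level surgery strategy from the two tri-state flags.

    PMTR = resection of both primary and metastatic sites; PTR_only =
    primary only; MTR_only = metastasectomy only; NoSurgery = neither.
    Unknown flags violate eligibility and raise.
    """
    if surgery_primary not in ("yes", "no") or surgery_mets not in ("yes", "no"):
        raise ValueError(
            "surgery flags must be known (yes/no) after eligibility filtering; "
            f"got ({surgery_primary!r}, {surgery_mets!r})")
    if surgery_primary == "yes":
        return "PMTR" if surgery_mets == "yes" else "PTR_only"
    return "MTR_only" if surgery_mets == "yes" else "NoSurgery"


def treatment_group_column(df: pd.DataFrame) -> pd.Series:
    """Vectorized treatment-group assignment."""
    sp, sm = df["surgery_primary"], df["surgery_mets"]
    if ((~sp.isin(["yes", "no"])) | (~sm.isin(["yes", "no"]))).any():
        raise ValueError("surgery flags contain 'unknown'; filter first")
    out = pd.Series("NoSurgery", index=df.index, dtype=object)
    out[(sp == "yes") & (sm == "yes")] = "PMTR"
    out[(sp == "yes") & (sm == "no")] = "PTR_only"
    out[(sp == "no") & (sm == "yes")] = "MTR_only"
    return out


# ---------------------------------------------------------------------------
# HSA merging
# ---------------------------------------------------------------------------

def merge_small_hsas(records: pd.DataFrame, region_coords: dict,
                     min_count: int = 50) -> dict[str, str]:
    """Combine each HSA with fewer than ``min_count`` cases into its nearest
    neighbour until every merged region holds at least ``min_count``.

    The smallest undersized region is merged first, into the region with the
    nearest patient-weighted centroid (Euclidean distance; distance ties and
    size ties break lexicographically by region id).  The surviving region
    keeps the target's id.  Returns a mapping original id -> merged id which
    is idempotent (merged ids map to themselves) and conserves patient
    counts.
    """
    counts = records["hsa_id"].value_counts().to_dict()
    missing = [h for h in counts if h not in region_coords]
    if missing:
        raise ValueError(f"regions without coordinates: {sorted(missing)}")
    total = sum(counts.values())
    if total < min_count:
        raise ValueError(
            f"total cohort ({total}) smaller than min_count ({min_count})")

    regions = {h: {"n": n, "xy": np.asarray(region_coords[h], dtype=float),
                   "members": [h]} for h, n in counts.items()}

    while True:
        small = [h for h, r in regions.items() if r["n"] < min_count]
        if not small or len(regions) == 1:
            break
        src = min(small, key=lambda h: (regions[h]["n"], h))
        others = [h for h in regions if h != src]
        sxy = regions[src]["xy"]
        tgt = min(others, key=lambda h: (float(np.hypot(*(regions[h]["xy"] - sxy))), h))
        a, b = regions[src], regions[tgt]
        n = a["n"] + b["n"]
        xy = (a["n"] * a["xy"] + b["n"] * b["xy"]) / n
        regions[tgt] = {"n": n, "xy": xy, "members": a["members"] + b["members"]}
        del regions[src]

    mapping = {}
    for tgt, r in regions.items():
        for m in r["members"]:
            mapping[m] = tgt
    return mapping
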