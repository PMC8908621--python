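"""Regional instrument construction and first-stage diagnostics.

The instrument is the (merged) health service area's treatment rate,
dichotomized at the unweighted median across regions ("below median" vs
"equal to or above the median").  Patients — not regions — are the analysis
units: each patient carries their region's level.  The first stage is a
stratified logistic regression of the treatment indicator on the binary
instrument; because the per-stratum model (intercept + instrument) is
saturated, its maximum-likelihood fit reproduces the stratum x instrument
cell proportions exactly, and the residual is the observed indicator minus
the predicted probability.

Instrument strength is summarized by the partial F statistic for adding the
instrument to a stratum-fixed-effects linear-probability model (the common
econometric first-stage report; values above 10 are conventionally "strong");
the logistic likelihood-ratio statistic is reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RegionRates", "FirstStageFit", "compute_hsa_rates", "dichotomize_rate",
    "collapse_race", "define_strata", "fit_first_stage", "first_stage_f",
    "weighted_pearson",
]

RACE3_LABELS = ("NHW", "NHB", "others")


def collapse_race(race: pd.Series) -> pd.Series:
    """Collapse the four-level race category to the three analysis levels
    (non-Hispanic white, non-Hispanic black, others; Hispanic -> others)."""
    out = pd.Series("others", index=race.index, dtype=object)
    out[race == "non-Hispanic white"] = "NHW"
    out[race == "non-Hispanic black"] = "NHB"
    return out


def compute_hsa_rates(records: pd.DataFrame, treated) -> pd.DataFrame:
    """Per-region patient counts and treatment rates.

    Parameters
    ----------
    records : cohort with (merged) ``hsa_id``.
    treated : boolean array-like aligned with ``records`` — the treatment
        predicate evaluated per patient.

    Returns a frame indexed by ``hsa_id`` with columns ``n`` and ``rate``.
    """
    tr = np.asarray(treated, dtype=float)
    if tr.shape[0] != len(records):
        raise ValueError("treated must align with records")
    g = pd.DataFrame({"hsa_id": records["hsa_id"].values, "treated": tr}) \
        .groupby("hsa_id")["treated"]
    out = pd.DataFrame({"n": g.size(), "rate": g.mean()})
    if (out["n"] == 0).any():
        raise ValueError("empty region after filtering")
    return out


def dichotomize_rate(region_table: pd.DataFrame, rate_col: str = "rate",
                     level_col: str = "level") -> pd.DataFrame:
    """Add a high/low level column: high iff rate >= median across regions.

    The median is the conventional interpolated median, unweighted across
    the merged regions.  If every rate is identical all regions are "high"
    (the boundary of the >= rule) and a warning is emitted.
    """
    if len(region_table) < 2:
        raise ValueError("need at least two regions to dichotomize")
    rates = region_table[rate_col].to_numpy(dtype=float)
    med = float(np.median(rates))
    out = region_table.copy()
    out[level_col] = np.where(rates >= med, "high", "low")
    if (out[level_col] == "high").all() and np.ptp(rates) == 0:
        warnings.warn("all regional rates identical; every region classified "
                      "'high' by the >= median rule", stacklevel=2)
    return out


def define_strata(records: pd.DataFrame, region_levels: pd.Series,
                  ) -> pd.Series:
    """Stratum label per patient: collapsed race x other-treatment rate level.

    ``region_levels`` maps (merged) hsa_id -> "high"/"low" for the
    *opposite* treatment's regional rate (PTR rate when analyzing PMTR and
    vice versa).  At most 6 strata result.
    """
    race3 = collapse_race(records["race"])
    lev = records["hsa_id"].map(region_levels)
    if lev.isna().any():
        missing = sorted(records.loc[lev.isna(), "hsa_id"].unique())
        raise ValueError(f"regions missing a rate level: {missing}")
    return race3.str.cat(lev, sep="|")


@dataclass
class FirstStageFit:
    """Stratified first-stage logistic fit and diagnostics.

    ``usable`` marks patients in strata with treatment variation and no
    complete separation; excluded strata contribute no instrument
    information and destabilize ML fits, so both stages drop them (their
    labels are listed in ``excluded_strata``).
    """

    coefficients: dict          # stratum -> {"intercept": ..., "instrument": ...}
    predicted: np.ndarray       # P(treated | stratum, instrument), NaN if unusable
    residual: np.ndarray        # observed - predicted, NaN if unusable
    usable: np.ndarray          # boolean per patient
    excluded_strata: list
    f_statistic: float
    f_df: tuple[int, int]
    lr_statistic: float
    converged: bool = True

    def diagnostics_dict(self) -> dict:
        return {
            "f_statistic": self.f_statistic,
            "f_df": list(self.f_df),
            "lr_statistic": self.lr_statistic,
            "n_usable": int(self.usable.sum()),
            "excluded_strata": list(self.excluded_strata),
            "coefficients": self.coefficients,
        }


def _logit(p):
    return np.log(p) - np.log1p(-p)


def fit_first_stage(strata, instrument_high, treated) -> FirstStageFit:
    """Fit the stratified logistic first stage and compute residuals.

    Within each stratum the model is logit P(T=1) = a + b * Z with binary
    Z (region rate level).  The design is saturated, so the exact MLE puts
    the predicted probability at each stratum x Z cell's observed treatment
    proportion; residual = T - predicted.  Strata with no treatment
    variation, a missing instrument cell, or a pure (0 or 1) cell —
    complete separation — are flagged unusable.

    Returns also the instrument-strength diagnostics over the usable
    patients (see :func:`first_stage_f`).
    """
    s = np.asarray(strata)
    z = np.asarray(instrument_high, dtype=bool)
    t = np.asarray(treated, dtype=float)
    n = t.size
    predicted = np.full(n, np.nan)
    residual = np.full(n, np.nan)
    usable = np.zeros(n, dtype=bool)
    coefs = {}
    excluded = []
    for lab in np.unique(s):
        m = s == lab
        t0, t1 = t[m & ~z], t[m & z]
        if t0.size == 0 or t1.size == 0:
            excluded.append(str(lab))
            continue
        p0, p1 = t0.mean(), t1.mean()
        if p0 in (0.0, 1.0) or p1 in (0.0, 1.0):
            # includes the no-variation case; ML diverges (separation)
            excluded.append(str(lab))
            continue
        coefs[str(lab)] = {"intercept": float(_logit(p0)),
                           "instrument": float(_logit(p1) - _logit(p0)),
                           "p_low": float(p0), "p_high": float(p1),
                           "n": int(m.sum())}
        predicted[m] = np.where(z[m], p1, p0)
        residual[m] = t[m] - predicted[m]
        usable[m] = True
    if not usable.any():
        raise ValueError("no usable strata: every stratum lacks treatment "
                         "variation or an instrument cell")
    f, df = first_stage_f(s[usable], z[usable], t[usable])
    lr = _first_stage_lr(s[usable], z[usable], t[usable])
    return FirstStageFit(coefficients=coefs, predicted=predicted,
                         residual=residual, usable=usable,
                         excluded_strata=excluded, f_statistic=f, f_df=df,
                         lr_statistic=lr)


def first_stage_f(strata, instrument_high, treated) -> tuple[float, tuple[int, int]]:
    """Partial F for adding the instrument to a stratum-fixed-effects
    linear-probability model of treatment.

    F = ((RSS_restricted - RSS_full) / 1) / (RSS_full / (n - k)) with k the
    number of parameters of the full model.  A constant instrument explains
    nothing: F = 0 with a warning.
    """
    s = np.asarray(strata)
    z = np.asarray(instrument_high, dtype=float)
    t = np.asarray(treated, dtype=float)
    n = t.size
    if np.ptp(z) == 0:
        warnings.warn("instrument has zero variance; F = 0", stacklevel=2)
        labs = np.unique(s)
        return 0.0, (1, n - (labs.size + 1))
    dummies = (s[:, None] == np.unique(s)[None, :]).astype(float)
    Xr = dummies
    Xf = np.column_stack([dummies, z])
    rss_r = _rss(Xr, t)
    rss_f = _rss(Xf, t)
    k = Xf.shape[1]
    df = (1, n - k)
    f = max(0.0, (rss_r - rss_f)) / (rss_f / (n - k))
    return float(f), df


def _rss(X, y):
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r)


def _bin_ll(t):
    """Binomial log-likelihood of a cell at its own mean."""
    k, m = t.sum(), t.size
    p = k / m
    if p in (0.0, 1.0):
        return 0.0
    return k * np.log(p) + (m - k) * np.log1p(-p)


def _first_stage_lr(s, z, t) -> float:
    """Logistic likelihood-ratio statistic for the instrument, pooled over
    strata (saturated cells vs stratum-only cells)."""
    ll_full = ll_red = 0.0
    for lab in np.unique(s):
        m = s == lab
        ll_red += _bin_ll(t[m])
        ll_full += _bin_ll(t[m & (z == 1)]) + _bin_ll(t[m & (z == 0)])
    return float(2.0 * (ll_full - ll_red))


def weighted_pearson(x, y, w) -> float:
    """Pearson correlation of two per-region rates, weighted by patient count.

    Weighted means are subtracted; the statistic is the weighted covariance
    over the product of weighted standard deviations.  With equal weights it
    reduces to the ordinary Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (x.shape == y.shape == w.shape):
        raise ValueError("x, y, w must have equal length")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    wm = w / w.sum()
    xc = x - wm @ x
    yc = y - wm @ y
    vx = wm @ (xc * xc)
    vy = wm @ (yc * yc)
    if vx == 0 or vy == 0:
        raise ValueError("zero variance in x or y")
    return float((wm @ (xc * yc)) / np.sqrt(vx * vy))
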