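"""Self-contained survival numerics.

This module implements the survival machinery used by the two-stage
residual-inclusion (2SRI) pipeline:

* Kaplan–Meier product-limit curves with Greenwood variance, log–log
  pointwise confidence bands and a Brookmeyer–Crowley-style confidence
  interval for the median survival time;
* stratified Cox proportional-hazards regression by Newton iteration on
  the partial likelihood, with Efron (default) or Breslow tie handling;
* a per-patient gamma-frailty Cox model fitted by an EM algorithm with the
  frailty variance estimated by profile maximization of the marginal
  likelihood;
* the Durbin–Wu–Hausman endogeneity test (Wald test on the first-stage
  residual's coefficient in the second-stage model);
* a pooled treatment-by-sidedness interaction test.

All fits are deterministic given the data and tolerances: convergence is
declared when the relative log-likelihood change falls below 1e-9, with at
most 100 Newton iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

__all__ = [
    "KMCurve",
    "CoxFit",
    "DWHResult",
    "km_estimate",
    "cox_fit",
    "cox_frailty_fit",
    "durbin_wu_hausman",
    "interaction_test",
    "ConvergenceError",
]

REL_TOL = 1e-9
MAX_NEWTON_ITER = 100


class ConvergenceError(RuntimeError):
    """Raised when a Newton or EM loop fails to converge; carries the trace."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------


@dataclass
class KMCurve:
    """Product-limit survival curve.

    ``median`` is the first time at which the curve drops to <= 0.5 (NaN if
    it never does).  ``median_ci`` inverts the log–log transformed pointwise
    confidence band at 0.5; either bound may be NaN when the corresponding
    band never crosses 0.5 within follow-up.
    """

    times: np.ndarray          # distinct event times, ascending (months)
    survival: np.ndarray       # S(t) at each event time, nonincreasing
    at_risk: np.ndarray        # risk-set size just before each event time
    n_events: np.ndarray       # deaths at each event time
    ci_lower: np.ndarray       # pointwise log–log 95% band
    ci_upper: np.ndarray
    median: float              # NaN if survival never reaches 0.5
    median_ci: tuple[float, float]

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time ``t``."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _first_crossing(times: np.ndarray, curve: np.ndarray) -> float:
    """First time at which a nonincreasing step curve is <= 0.5."""
    below = np.nonzero(curve <= 0.5 + 1e-12)[0]
    return float(times[below[0]]) if below.size else float("nan")


def km_estimate(times, events, alpha: float = 0.05) -> KMCurve:
    """Kaplan–Meier estimate of the survival function.

    Parameters
    ----------
    times : array-like of nonnegative follow-up times (months).
    events : array-like of booleans, True for death.
    alpha : two-sided level for the pointwise band (default 0.05).

    A cohort with no events yields S ≡ 1 and an undefined (NaN) median —
    this is not an error.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=bool)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a nonempty 1-D array")
    if np.any(t < 0) or np.any(np.isnan(t)):
        raise ValueError("follow-up times must be nonnegative and known")
    if d.shape != t.shape:
        raise ValueError("times and events must have equal length")

    order = np.argsort(t, kind="stable")
    t, d = t[order], d[order]
    n = t.size

    event_times = np.unique(t[d])
    if event_times.size == 0:
        return KMCurve(
            times=np.empty(0), survival=np.empty(0), at_risk=np.empty(0, int),
            n_events=np.empty(0, int), ci_lower=np.empty(0), ci_upper=np.empty(0),
            median=float("nan"), median_ci=(float("nan"), float("nan")),
        )

    # risk set just before each event time; deaths at each event time
    at_risk = n - np.searchsorted(t, event_times, side="left")
    _, deaths = np.unique(t[d], return_counts=True)

    frac = 1.0 - deaths / at_risk
    surv = np.cumprod(frac)

    # Greenwood variance on the log–log scale
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.cumsum(deaths / (at_risk * (at_risk - deaths)))
        logS = np.log(surv)
        se_cloglog = np.sqrt(gw) / np.abs(logS)
    z = stats.norm.ppf(1 - alpha / 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.log(-logS)
        lo = np.exp(-np.exp(theta + z * se_cloglog))
        hi = np.exp(-np.exp(theta - z * se_cloglog))
    # S == 1 (no drop yet) or S == 0 degenerate points
    lo = np.where(surv <= 0, 0.0, np.where(surv >= 1, 1.0, lo))
    hi = np.where(surv <= 0, 0.0, np.where(surv >= 1, 1.0, hi))

    median = _first_crossing(event_times, surv)
    # Median CI: invert each pointwise band curve at 0.5 (the convention of
    # survfit and lifelines).  The lower band crosses 0.5 first, so it gives
    # the CI's lower bound; the upper band gives the upper bound.
    med_lo = _first_crossing(event_times, lo)
    med_hi = _first_crossing(event_times, hi)
    return KMCurve(
        times=event_times, survival=surv, at_risk=at_risk, n_events=deaths,
        ci_lower=lo, ci_upper=hi, median=median, median_ci=(med_lo, med_hi),
    )


# ---------------------------------------------------------------------------
# Cox partial likelihood machinery
# ---------------------------------------------------------------------------


class _CoxData:
    """Pre-sorted arrays for fast repeated partial-likelihood evaluation.

    Patients are sorted by (stratum, time); risk-set sums are suffix sums of
    per-(stratum, time) group totals within each stratum, so one pass of
    cumulative sums serves every Newton iteration.  The structure is reused
    across the many refits of the frailty EM loop.
    """

    def __init__(self, X, times, events, strata=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != np.asarray(times).shape[0]:
            X = X.T
        t = np.asarray(times, dtype=float)
        d = np.asarray(events, dtype=bool)
        n = t.size
        if strata is None:
            s = np.zeros(n, dtype=int)
        else:
            _, s = np.unique(np.asarray(strata), return_inverse=True)
        if np.any(np.isnan(X)):
            raise ValueError("covariates contain missing values")
        if np.any(t < 0):
            raise ValueError("times must be nonnegative")

        order = np.lexsort((t, s))
        self.X = X[order]
        self.t = t[order]
        self.d = d[order]
        self.s = s[order]
        self.order = order
        self.n, self.p = self.X.shape

        # group = run of equal (stratum, time)
        new_group = np.ones(n, dtype=bool)
        new_group[1:] = (self.t[1:] != self.t[:-1]) | (self.s[1:] != self.s[:-1])
        self.grp_start = np.nonzero(new_group)[0]
        self.grp_id = np.cumsum(new_group) - 1
        self.n_grp = self.grp_start.size
        self.grp_stratum = self.s[self.grp_start]

        # deaths per group
        self.grp_deaths = np.add.reduceat(self.d.astype(float), self.grp_start)
        # stratum boundaries in group space
        first_grp = np.ones(self.n_grp, dtype=bool)
        first_grp[1:] = self.grp_stratum[1:] != self.grp_stratum[:-1]
        self.strat_first_grp = np.nonzero(first_grp)[0]
        self.strat_of_grp = np.cumsum(first_grp) - 1

        # per-event "slot" arrays for Efron correction
        ev_grp = np.nonzero(self.grp_deaths > 0)[0]
        self.ev_grp = ev_grp
        dk = self.grp_deaths[ev_grp].astype(int)
        self.slot_grp = np.repeat(ev_grp, dk)
        self.slot_l = np.arange(self.slot_grp.size) - np.repeat(
            np.concatenate(([0], np.cumsum(dk)[:-1])), dk)
        self.slot_frac = self.slot_l / np.repeat(dk, dk)
        self.event_mask = self.d
        # events per stratum (to validate)
        if np.any(np.bincount(self.s, weights=self.d.astype(float)) == 0):
            warnings.warn("a stratum contains no events and contributes nothing",
                          stacklevel=2)

    def _suffix_within_stratum(self, grp_vals):
        """Suffix cumulative sum of per-group values within each stratum."""
        out = np.cumsum(grp_vals[::-1], axis=0)[::-1]
        # the global suffix sum includes later strata; subtract their totals
        strat_tot = np.add.reduceat(grp_vals, self.strat_first_grp, axis=0)
        tail = np.cumsum(strat_tot[::-1], axis=0)[::-1]
        tail_after = np.zeros_like(strat_tot)
        tail_after[:-1] = tail[1:]
        nxt = tail_after[self.strat_of_grp]
        return out - nxt

    def loglik_grad_hess(self, beta, offset=None, ties="efron",
                         want_derivs=True):
        """Partial log-likelihood, gradient and Hessian at ``beta``.

        ``offset`` enters the linear predictor additively (log-frailty).
        """
        eta = self.X @ beta
        if offset is not None:
            eta = eta + offset
        eta = eta - eta.max()  # numeric guard; constant shift cancels in PL
        r = np.exp(eta)
        xr = self.X * r[:, None]

        g0 = np.add.reduceat(r, self.grp_start)
        S0 = self._suffix_within_stratum(g0)
        dmask = self.d
        # event-only sums within groups
        r_ev = np.where(dmask, r, 0.0)
        S0d = np.add.reduceat(r_ev, self.grp_start)

        if ties == "efron":
            frac = self.slot_frac
        elif ties == "breslow":
            frac = np.zeros_like(self.slot_frac)
        else:
            raise ValueError(f"unknown ties method: {ties!r}")

        phi = S0[self.slot_grp] - frac * S0d[self.slot_grp]
        ll = float(np.sum(eta[dmask]) - np.sum(np.log(phi)))
        if not want_derivs:
            return ll, None, None

        g1 = np.add.reduceat(xr, self.grp_start)
        S1 = self._suffix_within_stratum(g1)
        xr_ev = np.where(dmask[:, None], xr, 0.0)
        S1d = np.add.reduceat(xr_ev, self.grp_start)

        num1 = S1[self.slot_grp] - frac[:, None] * S1d[self.slot_grp]
        nu = num1 / phi[:, None]
        grad = self.X[dmask].sum(axis=0) - nu.sum(axis=0)

        xxr = (self.X[:, :, None] * self.X[:, None, :]).reshape(self.n, -1) * r[:, None]
        g2 = np.add.reduceat(xxr, self.grp_start)
        S2 = self._suffix_within_stratum(g2)
        xxr_ev = np.where(dmask[:, None], xxr, 0.0)
        S2d = np.add.reduceat(xxr_ev, self.grp_start)
        num2 = S2[self.slot_grp] - frac[:, None] * S2d[self.slot_grp]
        term1 = (num2 / phi[:, None]).sum(axis=0).reshape(self.p, self.p)
        term2 = nu.T @ nu
        hess = -(term1 - term2)
        return ll, grad, hess

    def baseline_cumhaz(self, beta, offset=None, ties="efron"):
        """Per-patient cumulative baseline hazard Λ0(t_i) within stratum.

        Uses Efron (or Breslow) hazard increments at each event time; a
        patient's own event group is included (standard convention).
        Returned in the sorted order of this structure.
        """
        eta = self.X @ beta
        if offset is not None:
            eta = eta + offset
        r = np.exp(eta)
        g0 = np.add.reduceat(r, self.grp_start)
        S0 = self._suffix_within_stratum(g0)
        r_ev = np.where(self.d, r, 0.0)
        S0d = np.add.reduceat(r_ev, self.grp_start)
        frac = self.slot_frac if ties == "efron" else np.zeros_like(self.slot_frac)
        phi = S0[self.slot_grp] - frac * S0d[self.slot_grp]
        # hazard increment per event group = sum of 1/phi over its slots
        inc = np.zeros(self.n_grp)
        np.add.at(inc, self.slot_grp, 1.0 / phi)
        # cumulative within stratum (prefix sum over groups)
        cum = np.cumsum(inc)
        # subtract prefix of previous strata
        strat_starts = self.strat_first_grp
        base = np.zeros(self.n_grp)
        start_cum = np.concatenate(([0.0], cum[strat_starts[1:] - 1])) \
            if strat_starts.size > 1 else np.zeros(1)
        base = start_cum[self.strat_of_grp]
        cum_within = cum - base
        return cum_within[self.grp_id], inc


@dataclass
class CoxFit:
    """Result of a (possibly frailty-adjusted) stratified Cox fit."""

    names: list[str]
    coef: np.ndarray                  # log hazard ratios
    cov: np.ndarray                   # inverse observed information
    loglik: float
    converged: bool
    iterations: int
    ties: str
    n: int
    n_events: int
    n_strata: int
    frailty_variance: float | None = None
    frailty_loglik: float | None = None   # marginal loglik at the optimum
    log_frailty: np.ndarray | None = None

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    def ci(self, alpha: float = 0.05) -> np.ndarray:
        z = stats.norm.ppf(1 - alpha / 2)
        return np.exp(np.column_stack([self.coef - z * self.se,
                                       self.coef + z * self.se]))

    @property
    def wald_p(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.coef / self.se
        return 2 * stats.norm.sf(np.abs(z))

    def coef_named(self, name: str) -> tuple[float, float]:
        i = self.names.index(name)
        return float(self.coef[i]), float(self.se[i])

    def summary_dict(self) -> dict:
        ci = self.ci()
        return {
            "coefficients": {
                nm: {"log_hr": float(b), "hr": float(np.exp(b)), "se": float(s),
                     "ci_low": float(lo), "ci_high": float(hi), "p": float(p)}
                for nm, b, s, (lo, hi), p in zip(
                    self.names, self.coef, self.se, ci, self.wald_p)
            },
            "loglik": self.loglik,
            "converged": self.converged,
            "iterations": self.iterations,
            "ties": self.ties,
            "n": self.n,
            "n_events": self.n_events,
            "n_strata": self.n_strata,
            "frailty_variance": self.frailty_variance,
        }


def _newton(data: _CoxData, offset=None, ties="efron", beta0=None,
            max_iter=MAX_NEWTON_ITER, rel_tol=REL_TOL):
    p = data.p
    beta = np.zeros(p) if beta0 is None else np.array(beta0, dtype=float)
    ll_prev = -np.inf
    trace = []
    for it in range(1, max_iter + 1):
        ll, g, H = data.loglik_grad_hess(beta, offset=offset, ties=ties)
        trace.append(ll)
        try:
            step = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                f"singular information matrix (collinear covariates?): {exc}",
                trace) from exc
        # step halving if likelihood would decrease
        new_beta = beta + step
        ll_new = data.loglik_grad_hess(new_beta, offset=offset, ties=ties,
                                       want_derivs=False)[0]
        halvings = 0
        while ll_new < ll - 1e-12 and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            ll_new = data.loglik_grad_hess(new_beta, offset=offset, ties=ties,
                                           want_derivs=False)[0]
            halvings += 1
        beta = new_beta
        if np.isfinite(ll_prev) and \
                np.abs(ll_new - ll_prev) <= rel_tol * (np.abs(ll_prev) + 1.0):
            ll, g, H = data.loglik_grad_hess(beta, offset=offset, ties=ties)
            return beta, ll, H, it, True, trace
        ll_prev = ll_new
    raise ConvergenceError(
        f"Cox Newton iteration did not converge in {max_iter} steps", trace)


def cox_fit(X, times, events, strata=None, names: Sequence[str] | None = None,
            ties: str = "efron", offset=None, beta0=None) -> CoxFit:
    """Stratified Cox proportional-hazards fit by partial likelihood.

    Parameters
    ----------
    X : (n, p) covariate matrix (no missing values, no constant column).
    times, events : follow-up months and death indicators.
    strata : optional stratum labels; the baseline hazard is free per stratum.
    ties : "efron" (default; registry months are heavily tied) or "breslow".
    offset : optional per-patient additive linear-predictor term.

    The returned covariance is the inverse observed information at the
    optimum.
    """
    data = _CoxData(X, times, events, strata)
    off = None
    if offset is not None:
        off = np.asarray(offset, dtype=float)[data.order]
    beta, ll, H, iters, conv, _ = _newton(data, offset=off, ties=ties, beta0=beta0)
    cov = np.linalg.inv(-H)
    if names is None:
        names = [f"x{i}" for i in range(data.p)]
    return CoxFit(names=list(names), coef=beta, cov=cov, loglik=ll,
                  converged=conv, iterations=iters, ties=ties, n=data.n,
                  n_events=int(data.d.sum()),
                  n_strata=int(data.s.max()) + 1)


# ---------------------------------------------------------------------------
# Gamma frailty
# ---------------------------------------------------------------------------


def _frailty_em(data: _CoxData, theta: float, ties: str,
                beta0=None, w0=None, max_iter=500, rel_tol=1e-11):
    """EM for fixed frailty variance ``theta`` (per-patient gamma frailty).

    E-step: posterior mean frailty w_i = (nu + d_i) / (nu + M_i) with
    nu = 1/theta and M_i = Lambda0(t_i) exp(x_i beta); M excludes w_i itself.
    M-step: Cox fit with offset log w and baseline re-estimated with the
    offsets in the risk sums.  Plain EM converges at a slow geometric rate,
    which makes the profile marginal likelihood unusable for selecting theta,
    so cycles are accelerated with SQUAREM extrapolation on log w.  Returns
    the fitted beta, log-frailties and the profile marginal log-likelihood.
    """
    n = data.n
    d = data.d.astype(float)
    if theta <= 0:
        beta, ll, H, iters, conv, _ = _newton(data, ties=ties, beta0=beta0)
        # marginal loglik at theta=0: full Breslow/Efron likelihood
        cumhaz, inc = data.baseline_cumhaz(beta, ties=ties)
        eta = data.X @ beta
        M = cumhaz * np.exp(eta)
        log_inc = np.where(inc > 0, np.log(np.maximum(inc, 1e-300)), 0.0)
        ll_marg = float(np.sum(d * (eta + log_inc[data.grp_id])) - np.sum(M))
        return beta, np.zeros(n), ll_marg, H, iters, True

    nu = 1.0 / theta
    logw = np.zeros(n) if w0 is None else np.log(np.asarray(w0, dtype=float))
    state = {"beta": np.zeros(data.p) if beta0 is None
             else np.array(beta0, dtype=float), "H": None}

    def em_step(logw):
        """One EM cycle; returns new log w and the marginal loglik there.

        A single Newton step updates beta per cycle (the joint fixed point is
        unchanged and the step is cheap); the final beta is polished by a
        full Newton solve after the profile search.
        """
        beta = state["beta"]
        _, g, H = data.loglik_grad_hess(beta, offset=logw, ties=ties)
        try:
            beta = beta + np.linalg.solve(-H, g)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information in frailty EM: {exc}") \
                from exc
        state["beta"], state["H"] = beta, H
        cumhaz, inc = data.baseline_cumhaz(beta, offset=logw, ties=ties)
        eta = data.X @ beta
        M = cumhaz * np.exp(eta)
        log_inc = np.where(inc > 0, np.log(np.maximum(inc, 1e-300)), 0.0)
        ll_marg = float(
            np.sum(d * (eta + log_inc[data.grp_id]))
            + n * (nu * np.log(nu) - gammaln(nu))
            + np.sum(gammaln(nu + d) - (nu + d) * np.log(nu + M))
        )
        return np.log(nu + d) - np.log(nu + M), ll_marg

    ll_prev = -np.inf
    it = 0
    while it < max_iter:
        # SQUAREM (S3) cycle: two EM maps, extrapolate, one stabilizing map
        lw1, ll1 = em_step(logw)
        lw2, ll2 = em_step(lw1)
        it += 2
        r = lw1 - logw
        v = lw2 - lw1 - r
        vn = np.linalg.norm(v)
        if vn < 1e-14:
            logw, ll = lw2, ll2
        else:
            alpha = -np.linalg.norm(r) / vn
            alpha = min(-1.0, alpha)  # never shorter than a plain EM step
            cand = logw - 2.0 * alpha * r + alpha * alpha * v
            logw, ll = em_step(cand)
            it += 1
            if not np.isfinite(ll) or ll < ll2:
                logw, ll = lw2, ll2  # fall back to the plain EM iterate
        if np.isfinite(ll_prev) and \
                abs(ll - ll_prev) <= rel_tol * (abs(ll_prev) + 1.0):
            break
        ll_prev = ll
    else:
        return state["beta"], logw, ll, state["H"], max_iter, False
    # polish beta to full convergence at the final frailty values
    beta, _, H, _, _, _ = _newton(data, offset=logw, ties=ties,
                                  beta0=state["beta"])
    lw_f, ll_f = em_step(logw)
    return beta, logw, ll_f, H, it, True


_THETA_GRID = (0.0, 0.1, 0.3, 0.7, 1.5)
_THETA_MAX = 4.0


def cox_frailty_fit(X, times, events, strata=None,
                    names: Sequence[str] | None = None, ties: str = "efron",
                    frailty_variance: float | None = None) -> CoxFit:
    """Stratified Cox fit with a per-patient gamma frailty term.

    The frailty multiplies the hazard, has mean 1 and variance theta.  For
    fixed theta the model is fitted by EM (posterior-mean frailties enter as
    offsets); theta itself is estimated by profile maximization of the
    marginal log-likelihood over a coarse grid followed by Brent refinement.
    ``frailty_variance`` fixes theta instead of estimating it; 0 reproduces
    the plain :func:`cox_fit` coefficients.

    The covariance matrix conditions on the fitted frailties and theta
    (penalized-likelihood practice); it therefore slightly understates the
    variance when theta is large.
    """
    data = _CoxData(X, times, events, strata)
    if names is None:
        names = [f"x{i}" for i in range(np.atleast_2d(np.asarray(X)).shape[-1])]

    cache: dict[float, tuple] = {}
    state = {"beta": None, "w": None}

    def profile(theta: float):
        theta = max(0.0, float(theta))
        key = round(theta, 10)
        if key not in cache:
            w0 = None
            if state["w"] is not None and theta > 0:
                w0 = state["w"]
            res = _frailty_em(data, theta, ties, beta0=state["beta"], w0=w0)
            cache[key] = res
            state["beta"] = res[0]
            if theta > 0:
                state["w"] = np.exp(res[1])
        return cache[key]

    if frailty_variance is not None:
        theta_hat = float(frailty_variance)
        beta, logw, ll_marg, H, iters, conv = profile(theta_hat)
    else:
        grid_ll = [profile(th)[2] for th in _THETA_GRID]
        best = int(np.argmax(grid_ll))
        if best == 0:
            # maximum at or near the boundary: refine on [0, first grid point]
            res = minimize_scalar(lambda th: -profile(th)[2],
                                  bounds=(0.0, _THETA_GRID[1]),
                                  method="bounded",
                                  options={"xatol": 5e-3, "maxiter": 30})
            theta_hat = float(res.x) if -res.fun > grid_ll[0] + 1e-10 else 0.0
        else:
            lo = _THETA_GRID[best - 1]
            hi = _THETA_GRID[best + 1] if best + 1 < len(_THETA_GRID) else _THETA_MAX
            res = minimize_scalar(lambda th: -profile(th)[2],
                                  bounds=(lo, hi), method="bounded",
                                  options={"xatol": 5e-3, "maxiter": 40})
            theta_hat = float(res.x)
        beta, logw, ll_marg, H, iters, conv = profile(theta_hat)
        if not conv:
            raise ConvergenceError(
                f"frailty EM did not converge at theta={theta_hat:.4g}",
                trace=[ll_marg])

    cov = np.linalg.inv(-H)
    # partial loglik of the final offset fit, for reporting
    ll_partial = data.loglik_grad_hess(beta, offset=(logw if theta_hat > 0 else None),
                                       ties=ties, want_derivs=False)[0]
    inv_order = np.argsort(data.order)
    return CoxFit(names=list(names), coef=beta, cov=cov, loglik=float(ll_partial),
                  converged=conv, iterations=iters, ties=ties, n=data.n,
                  n_events=int(data.d.sum()), n_strata=int(data.s.max()) + 1,
                  frailty_variance=theta_hat, frailty_loglik=float(ll_marg),
                  log_frailty=logw[inv_order])


# ---------------------------------------------------------------------------
# Endogeneity and interaction tests
# ---------------------------------------------------------------------------


@dataclass
class DWHResult:
    """Durbin–Wu–Hausman endogeneity test.

    A small p-value indicates the treatment is endogenous — the naive
    multivariable model is likely biased and the IV analysis is warranted.
    """

    residual_coefficient: float
    se: float
    p_value: float


def durbin_wu_hausman(fit: CoxFit, residual_name: str = "residual") -> DWHResult:
    """Wald test on the first-stage residual's coefficient in the second stage."""
    if residual_name not in fit.names:
        raise ValueError(
            f"fit has no term {residual_name!r}; second stage must include the "
            "first-stage residual")
    b, se = fit.coef_named(residual_name)
    z = b / se if se > 0 else 0.0
    p = 1.0 if b == 0 else 2 * stats.norm.sf(abs(z))
    return DWHResult(residual_coefficient=b, se=se, p_value=p)


def interaction_test(treatment, sidedness, residual, times, events,
                     strata, frailty: bool = True) -> tuple[float, CoxFit]:
    """Treatment-by-sidedness interaction in a pooled second-stage model.

    The pooled model carries treatment, a sidedness indicator (implicit in
    the strata), the treatment × sidedness product and subgroup-specific
    first-stage residuals; baseline hazards are stratified by subgroup ×
    stratum so the sidedness main effect is absorbed.  Returns the two-sided
    Wald p-value for the interaction coefficient and the full fit.
    """
    side = np.asarray(sidedness)
    subgroups = np.unique(side)
    if subgroups.size < 2:
        raise ValueError("interaction test needs both sidedness subgroups")
    tr = np.asarray(treatment, dtype=float)
    res = np.asarray(residual, dtype=float)
    is_second = (side == subgroups[1]).astype(float)
    X = np.column_stack([
        tr,
        tr * is_second,
        res * (1.0 - is_second),
        res * is_second,
    ])
    names = ["treatment", "treatment_x_side", "residual_g1", "residual_g2"]
    pooled_strata = np.char.add(np.char.add(side.astype(str), "||"),
                                np.asarray(strata).astype(str))
    fitter = cox_frailty_fit if frailty else cox_fit
    fit = fitter(X, times, events, strata=pooled_strata, names=names)
    i = names.index("treatment_x_side")
    z = fit.coef[i] / fit.se[i]
    return float(2 * stats.norm.sf(abs(z))), fit
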