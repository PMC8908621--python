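"""Independent brute-force oracles used only by the tests.

These are deliberately naive (loops, no shared code with the package) so
they provide a second, independent route to the same quantities.
"""

import numpy as np


def km_oracle(times, events):
    """Product-limit estimator by explicit risk-set counting.

    Returns (event_times, survival) with one entry per distinct death time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    uniq = sorted(set(times[events]))
    surv = []
    s = 1.0
    for t in uniq:
        n_at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & events))
        s *= 1.0 - d / n_at_risk
        surv.append(s)
    return np.array(uniq), np.array(surv)


def breslow_loglik_oracle(beta, x, times, events):
    """Breslow-ties Cox partial log-likelihood, single covariate, by loops."""
    x = np.asarray(x, dtype=float)
    eta = beta * x
    ll = 0.0
    for i in np.nonzero(events)[0]:
        risk = times >= times[i]
        ll += eta[i] - np.log(np.sum(np.exp(eta[risk])))
    return ll


def efron_loglik_oracle(beta, x, times, events):
    """Efron-ties Cox partial log-likelihood, single covariate, by loops."""
    x = np.asarray(x, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    eta = beta * x
    r = np.exp(eta)
    ll = 0.0
    for t in sorted(set(times[events])):
        death = (times == t) & events
        d = int(death.sum())
        risk_sum = float(np.sum(r[times >= t]))
        death_sum = float(np.sum(r[death]))
        ll += float(np.sum(eta[death]))
        for l in range(d):
            ll -= np.log(risk_sum - (l / d) * death_sum)
    return ll


def maximize_1d(fun, lo=-6.0, hi=6.0, tol=1e-10):
    """Golden-section maximization of a scalar function."""
    from scipy.optimize import minimize_scalar
    res = minimize_scalar(lambda b: -fun(b), bounds=(lo, hi),
                          method="bounded", options={"xatol": tol})
    return float(res.x)


def offset_efron_loglik_oracle(beta, X, offset, times, events, strata):
    """Multi-covariate stratified Efron partial log-likelihood with offsets,
    by loops (for checking fitted optima, e.g. the frailty fit's beta)."""
    X = np.asarray(X, dtype=float)
    eta = X @ np.asarray(beta, dtype=float) + np.asarray(offset, dtype=float)
    r = np.exp(eta)
    strata = np.asarray(strata)
    ll = 0.0
    for s in np.unique(strata):
        sm = strata == s
        ts, es, rs, etas = times[sm], events[sm], r[sm], eta[sm]
        for t in sorted(set(ts[es])):
            death = (ts == t) & es
            d = int(death.sum())
            risk_sum = float(np.sum(rs[ts >= t]))
            death_sum = float(np.sum(rs[death]))
            ll += float(np.sum(etas[death]))
            for l in range(d):
                ll -= np.log(risk_sum - (l / d) * death_sum)
    return ll
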