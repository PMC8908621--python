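"""Survival engine: Kaplan–Meier, stratified Cox (Efron/Breslow), gamma
frailty, endogeneity and interaction tests — all checked against independent
oracles (brute-force product limit, hand-coded partial likelihoods,
lifelines, R survival)."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from ivsurv.survival import (ConvergenceError, CoxFit, cox_fit,
                             cox_frailty_fit, durbin_wu_hausman,
                             interaction_test, km_estimate, _CoxData)
from oracles import (breslow_loglik_oracle, efron_loglik_oracle, km_oracle,
                     maximize_1d, offset_efron_loglik_oracle)


class TestKaplanMeier:
    def test_three_deaths_by_hand(self):
        km = km_estimate([1, 2, 3], [True, True, True])
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        assert km.median == 2.0

    def test_all_censored(self):
        km = km_estimate([5, 8, 13], [False, False, False])
        assert km.times.size == 0
        assert np.isnan(km.median)

    def test_mixed_censoring_matches_oracle(self, rng):
        t = rng.integers(1, 15, 20).astype(float)
        e = rng.random(20) < 0.6
        km = km_estimate(t, e)
        ot, osurv = km_oracle(t, e)
        assert np.allclose(km.times, ot)
        assert np.allclose(km.survival, osurv, atol=1e-12)

    def test_matches_lifelines_including_median_ci(self, rng):
        from lifelines import KaplanMeierFitter
        from lifelines.utils import median_survival_times
        t = rng.exponential(20, 300).round() + 1
        e = rng.random(300) < 0.75
        km = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        ref = kmf.survival_function_.loc[km.times, "KM_estimate"].to_numpy()
        assert np.allclose(km.survival, ref, atol=1e-12)
        assert km.median == kmf.median_survival_time_
        ref_ci = median_survival_times(kmf.confidence_interval_).to_numpy()[0]
        assert km.median_ci == pytest.approx(tuple(ref_ci), nan_ok=True)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1.0, 2.0], [True, True])


def _binary_fixture(rng, n=30, tied=False):
    x = (rng.random(n) < 0.5).astype(float)
    t = rng.exponential(1 / np.exp(0.7 * x))
    if tied:
        t = np.ceil(t * 4)
    e = rng.random(n) < 0.8
    return x, t, e


class TestCox:
    def test_identical_groups_give_zero_coefficient(self, rng):
        t = rng.exponential(10, 25)
        e = rng.random(25) < 0.8
        x = np.r_[np.zeros(25), np.ones(25)]
        fit = cox_fit(x[:, None], np.r_[t, t], np.r_[e, e])
        assert abs(fit.coef[0]) < 1e-6

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_untied_fixture_matches_1d_oracle(self, rng, ties):
        x, t, e = _binary_fixture(rng, tied=False)
        fit = cox_fit(x[:, None], t, e, ties=ties)
        oracle = {"efron": efron_loglik_oracle,
                  "breslow": breslow_loglik_oracle}[ties]
        b_ref = maximize_1d(lambda b: oracle(b, x, t, e))
        assert fit.coef[0] == pytest.approx(b_ref, abs=1e-6)

    def test_tied_fixture_efron_differs_and_both_match_oracles(self, rng):
        x, t, e = _binary_fixture(rng, tied=True)
        fe = cox_fit(x[:, None], t, e, ties="efron")
        fb = cox_fit(x[:, None], t, e, ties="breslow")
        assert fe.coef[0] != pytest.approx(fb.coef[0], abs=1e-4)
        be = maximize_1d(lambda b: efron_loglik_oracle(b, x, t, e))
        bb = maximize_1d(lambda b: breslow_loglik_oracle(b, x, t, e))
        assert fe.coef[0] == pytest.approx(be, abs=1e-6)
        assert fb.coef[0] == pytest.approx(bb, abs=1e-6)

    def test_matches_lifelines_stratified(self, rng):
        from lifelines import CoxPHFitter
        n = 400
        X = rng.normal(size=(n, 2))
        s = rng.integers(0, 3, n)
        t = np.ceil(rng.exponential(1 / np.exp(0.5 * X[:, 0] - 0.3 * X[:, 1])) * 8)
        e = rng.random(n) < 0.8
        fit = cox_fit(X, t, e, strata=s)
        df = pd.DataFrame({"t": t, "e": e, "x0": X[:, 0], "x1": X[:, 1],
                           "s": s})
        ref = CoxPHFitter().fit(df, "t", "e", strata=["s"])
        assert np.allclose(fit.coef, ref.params_.to_numpy(), atol=2e-5)
        assert np.allclose(fit.se, ref.standard_errors_.to_numpy(), atol=2e-5)

    def test_score_zero_and_loglik_above_null_at_optimum(self, rng):
        n = 300
        X = rng.normal(size=(n, 3))
        t = np.ceil(rng.exponential(1 / np.exp(X @ [0.4, -0.2, 0.0])) * 5)
        e = rng.random(n) < 0.7
        fit = cox_fit(X, t, e)
        data = _CoxData(X, t, e)
        ll, g, _ = data.loglik_grad_hess(fit.coef)
        ll0 = data.loglik_grad_hess(np.zeros(3), want_derivs=False)[0]
        assert np.linalg.norm(g) < 1e-6
        assert ll >= ll0

    def test_time_rescaling_leaves_coefficients_unchanged(self, rng):
        x, t, e = _binary_fixture(rng, n=60, tied=True)
        f1 = cox_fit(x[:, None], t, e)
        f2 = cox_fit(x[:, None], t * 30.4375, e)  # months -> days
        assert np.allclose(f1.coef, f2.coef, atol=1e-10)

    def test_collinear_covariates_raise(self, rng):
        x, t, e = _binary_fixture(rng, n=40)
        X = np.column_stack([x, x])
        with pytest.raises((ConvergenceError, np.linalg.LinAlgError)):
            cox_fit(X, t, e)

    def test_hr_ci_brackets_point_estimate(self, rng):
        x, t, e = _binary_fixture(rng, n=80)
        fit = cox_fit(x[:, None], t, e)
        lo, hi = fit.ci()[0]
        assert lo < fit.hr[0] < hi


class TestFrailty:
    def test_variance_zero_reproduces_plain_cox(self, rng):
        x, t, e = _binary_fixture(rng, n=120, tied=True)
        plain = cox_fit(x[:, None], t, e)
        frail = cox_frailty_fit(x[:, None], t, e, frailty_variance=0.0)
        assert np.allclose(frail.coef, plain.coef, atol=1e-6)
        assert frail.frailty_variance == 0.0

    def test_fixed_theta_matches_r_coxph(self, rng, tmp_path):
        # R survival's penalized gamma-frailty fit is the independent oracle
        n = 400
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(1 / (0.05 * np.exp(-0.8 * x + 0.5 * rng.normal(size=n))))
        e = t <= 100
        t = np.minimum(t, 100)
        fit = cox_frailty_fit(x[:, None], t, e, ties="breslow",
                              frailty_variance=0.3)
        csv = tmp_path / "d.csv"
        pd.DataFrame({"t": t, "e": e.astype(int), "x": x}).to_csv(csv,
                                                                  index=False)
        rscript = shutil.which("Rscript")
        out = subprocess.run(
            [rscript, "-e",
             f'library(survival); d<-read.csv("{csv}");'
             'f<-coxph(Surv(t,e)~x+frailty(1:nrow(d),distribution="gamma",'
             'theta=0.3),data=d,ties="breslow"); cat(coef(f)[1])'],
            capture_output=True, text=True, check=True)
        assert fit.coef[0] == pytest.approx(float(out.stdout), abs=1e-4)

    def test_returned_beta_maximizes_offset_partial_likelihood(self, rng):
        n = 150
        x = (rng.random(n) < 0.4).astype(float)
        fr = rng.gamma(2.0, 0.5, n)
        t = rng.exponential(1 / (0.05 * np.exp(-0.6 * x) * fr))
        e = t <= 80
        t = np.minimum(t, 80)
        s = rng.integers(0, 2, n)
        fit = cox_frailty_fit(x[:, None], t, e, strata=s,
                              frailty_variance=0.5)
        def obj(b):
            return offset_efron_loglik_oracle([b], x[:, None],
                                              fit.log_frailty, t, e, s)
        b0 = fit.coef[0]
        assert obj(b0) >= obj(b0 + 1e-3) - 1e-9
        assert obj(b0) >= obj(b0 - 1e-3) - 1e-9
        assert b0 == pytest.approx(maximize_1d(obj), abs=1e-5)

    def test_true_frailty_deattenuates_coefficient(self, rng):
        # gamma frailty var 0.5 attenuates the marginal effect; the frailty
        # fit should move the estimate back toward the conditional truth
        n = 4000
        x = (rng.random(n) < 0.5).astype(float)
        fr = rng.gamma(2.0, 0.5, n)
        t = rng.exponential(1 / (0.0433 * np.exp(-1.0 * x) * fr))
        e = t <= 120
        t = np.minimum(t, 120)
        plain = cox_fit(x[:, None], t, e)
        frail = cox_frailty_fit(x[:, None], t, e)
        assert frail.frailty_variance > 0
        assert frail.coef[0] < plain.coef[0]  # more negative, toward -1

    def test_no_frailty_data_yields_near_zero_variance(self, rng):
        # median estimated variance < 0.05 when the data carry no frailty
        thetas = []
        for _ in range(30):
            n = 5000
            x = (rng.random(n) < 0.5).astype(float)
            t = rng.exponential(1 / (0.0433 * np.exp(-0.5 * x)))
            e = t <= 120
            t = np.minimum(t, 120)
            thetas.append(cox_frailty_fit(x[:, None], t, e).frailty_variance)
        assert np.median(thetas) < 0.05


class TestDWH:
    def _fit_with_residual(self, coef, se):
        cov = np.diag([0.01, se ** 2])
        return CoxFit(names=["treatment", "residual"],
                      coef=np.array([-0.5, coef]), cov=cov, loglik=-10.0,
                      converged=True, iterations=3, ties="efron", n=100,
                      n_events=80, n_strata=1)

    def test_zero_coefficient_gives_p_one(self):
        res = durbin_wu_hausman(self._fit_with_residual(0.0, 0.2))
        assert res.p_value == 1.0

    def test_wald_p_two_sided(self):
        res = durbin_wu_hausman(self._fit_with_residual(0.392, 0.2))
        from scipy import stats
        assert res.p_value == pytest.approx(2 * stats.norm.sf(0.392 / 0.2))

    def test_missing_residual_term_raises(self):
        fit = CoxFit(names=["treatment"], coef=np.array([-0.5]),
                     cov=np.eye(1), loglik=-1, converged=True, iterations=1,
                     ties="efron", n=10, n_events=5, n_strata=1)
        with pytest.raises(ValueError, match="residual"):
            durbin_wu_hausman(fit)


class TestInteraction:
    def _subgroup(self, rng, n, loghr):
        # binary instrument cells so treatment and residual are separable
        z = rng.random(n) < 0.5
        p = np.where(z, 0.55, 0.25)
        tr = (rng.random(n) < p).astype(float)
        res = tr - p
        t = rng.exponential(1 / (0.05 * np.exp(loghr * tr)))
        e = t <= 100
        return tr, res, np.minimum(t, 100), e

    def test_duplicated_subgroup_gives_zero_interaction(self, rng):
        tr, res, t, e = self._subgroup(rng, 400, -0.7)
        p, fit = interaction_test(
            np.r_[tr, tr], np.r_[["left"] * 400, ["right"] * 400],
            np.r_[res, res], np.r_[t, t], np.r_[e, e],
            np.r_[["s"] * 400, ["s"] * 400], frailty=False)
        i = fit.names.index("treatment_x_side")
        assert abs(fit.coef[i]) < 1e-6
        assert p == pytest.approx(1.0, abs=1e-4)

    def test_detects_differential_effect(self, rng):
        rejections = 0
        for _ in range(15):
            tr1, res1, t1, e1 = self._subgroup(rng, 2000, -1.0)
            tr2, res2, t2, e2 = self._subgroup(rng, 2000, 0.0)
            p, _ = interaction_test(
                np.r_[tr1, tr2], np.r_[["left"] * 2000, ["right"] * 2000],
                np.r_[res1, res2], np.r_[t1, t2], np.r_[e1, e2],
                np.repeat("s", 4000), frailty=False)
            rejections += p < 0.05
        assert rejections >= 13

    def test_single_subgroup_raises(self, rng):
        tr, res, t, e = self._subgroup(rng, 100, -0.5)
        with pytest.raises(ValueError, match="both"):
            interaction_test(tr, np.repeat("left", 100), res, t, e,
                             np.repeat("s", 100))
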