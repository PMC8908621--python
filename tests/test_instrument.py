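"""Regional instrument, first-stage logistic fit and strength diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ivsurv.instrument import (collapse_race, compute_hsa_rates, define_strata,
                               dichotomize_rate, first_stage_f,
                               fit_first_stage, weighted_pearson)


def _region_frame(counts):
    return pd.DataFrame({"hsa_id": np.repeat(list(counts),
                                             list(counts.values()))})


class TestRates:
    def test_hand_arithmetic(self):
        df = _region_frame({"A": 50, "B": 60, "C": 55})
        treated = np.concatenate([np.ones(20), np.zeros(30),
                                  np.ones(10), np.zeros(50),
                                  np.ones(5), np.zeros(50)])
        out = compute_hsa_rates(df, treated)
        assert out.loc["A", "rate"] == pytest.approx(0.40)
        assert out.loc["B", "rate"] == pytest.approx(10 / 60)
        assert out.loc["C", "rate"] == pytest.approx(5 / 55)
        assert out["n"].sum() == 165

    def test_all_treated_region(self):
        df = _region_frame({"A": 10})
        out = compute_hsa_rates(df, np.ones(10))
        assert out.loc["A", "rate"] == 1.0


class TestDichotomize:
    def test_median_is_high(self):
        tab = pd.DataFrame({"rate": [0.2, 0.3, 0.4], "n": [10, 10, 10]},
                           index=["A", "B", "C"])
        out = dichotomize_rate(tab)
        assert list(out["level"]) == ["low", "high", "high"]

    def test_even_count_interpolated_median(self):
        tab = pd.DataFrame({"rate": [0.1, 0.2, 0.6, 0.8]},
                           index=list("ABCD"))
        out = dichotomize_rate(tab)  # median 0.4
        assert list(out["level"]) == ["low", "low", "high", "high"]

    def test_all_equal_rates_all_high_with_warning(self):
        tab = pd.DataFrame({"rate": [0.3, 0.3, 0.3]}, index=list("ABC"))
        with pytest.warns(UserWarning, match="identical"):
            out = dichotomize_rate(tab)
        assert (out["level"] == "high").all()


class TestStrata:
    def test_race_by_level_labels(self, record_frame):
        df = record_frame([
            {"race": "non-Hispanic white", "hsa_id": "H1"},
            {"race": "Hispanic", "hsa_id": "H2"},
            {"race": "non-Hispanic black", "hsa_id": "H1"},
        ])
        levels = pd.Series({"H1": "high", "H2": "low"})
        strata = define_strata(df, levels)
        assert list(strata) == ["NHW|high", "others|low", "NHB|high"]

    def test_hispanic_collapses_to_others(self):
        s = collapse_race(pd.Series(["Hispanic", "other",
                                     "non-Hispanic white"]))
        assert list(s) == ["others", "others", "NHW"]


class TestFirstStage:
    def test_saturated_predictions_equal_cell_proportions(self, rng):
        n = 400
        strata = rng.choice(["s1", "s2"], size=n)
        z = rng.random(n) < 0.5
        p = np.where(z, 0.55, 0.30)
        t = (rng.random(n) < p).astype(float)
        fit = fit_first_stage(strata, z, t)
        for lab in ("s1", "s2"):
            for zz in (True, False):
                cell = (strata == lab) & (z == zz)
                if cell.sum():
                    assert np.allclose(fit.predicted[cell],
                                       t[cell].mean(), atol=1e-8)
        # residuals center exactly within every stratum
        for lab in ("s1", "s2"):
            m = (strata == lab) & fit.usable
            assert abs(fit.residual[m].sum()) < 1e-8

    def test_matches_statsmodels_logit(self, rng):
        import statsmodels.api as sm
        n = 300
        z = rng.random(n) < 0.5
        t = (rng.random(n) < np.where(z, 0.6, 0.35)).astype(float)
        fit = fit_first_stage(np.repeat("s", n), z, t)
        X = sm.add_constant(z.astype(float))
        ml = sm.Logit(t, X).fit(disp=0)
        c = fit.coefficients["s"]
        assert c["intercept"] == pytest.approx(ml.params[0], abs=1e-6)
        assert c["instrument"] == pytest.approx(ml.params[1], abs=1e-6)

    def test_coefficient_recovery_within_3_se(self, rng):
        # logit p = -1 + 0.8 z, n = 500; closed-form MLE and its SE
        n = 500
        z = rng.random(n) < 0.5
        p = 1 / (1 + np.exp(-(-1 + 0.8 * z)))
        t = (rng.random(n) < p).astype(float)
        fit = fit_first_stage(np.repeat("s", n), z, t)
        c = fit.coefficients["s"]
        p0, p1 = c["p_low"], c["p_high"]
        n0, n1 = (~z).sum(), z.sum()
        se = np.sqrt(1 / (n0 * p0 * (1 - p0)) + 1 / (n1 * p1 * (1 - p1)))
        assert abs(c["instrument"] - 0.8) < 3 * se

    def test_separated_stratum_excluded(self):
        strata = np.array(["a"] * 10 + ["b"] * 40)
        z = np.array([False] * 5 + [True] * 5 + [False] * 20 + [True] * 20)
        t = np.array([1.0] * 10 + [0.0] * 10 + [1.0] * 10
                     + [0.0] * 5 + [1.0] * 15)
        fit = fit_first_stage(strata, z, t)
        assert "a" in fit.excluded_strata          # all treated: separation
        assert not fit.usable[strata == "a"].any()
        assert fit.usable[strata == "b"].all()

    def test_no_usable_strata_raises(self):
        with pytest.raises(ValueError, match="usable"):
            fit_first_stage(np.repeat("s", 10),
                            np.array([True] * 5 + [False] * 5),
                            np.ones(10))


class TestFStatistic:
    def test_constant_instrument_gives_zero(self):
        with pytest.warns(UserWarning, match="zero variance"):
            f, _ = first_stage_f(np.repeat("s", 20), np.zeros(20),
                                 np.r_[np.ones(10), np.zeros(10)])
        assert f == 0.0

    def test_strong_instrument_clears_cutoff(self, rng):
        n = 5000
        z = rng.random(n) < 0.5
        t = (rng.random(n) < np.where(z, 0.45, 0.20)).astype(float)  # gap 0.25
        f, _ = first_stage_f(np.repeat("s", n), z, t)
        assert f > 10

    def test_matches_statsmodels_partial_f(self, rng):
        import statsmodels.api as sm
        n = 600
        strata = rng.choice(["a", "b", "c"], size=n)
        z = (rng.random(n) < 0.5).astype(float)
        t = (rng.random(n) < 0.3 + 0.1 * z).astype(float)
        f, (df1, df2) = first_stage_f(strata, z, t)
        d = pd.get_dummies(pd.Series(strata), dtype=float).to_numpy()
        full = sm.OLS(t, np.column_stack([d, z])).fit()
        restricted = sm.OLS(t, d).fit()
        f_ref = float(full.compare_f_test(restricted)[0])
        assert f == pytest.approx(f_ref, rel=1e-8)
        assert (df1, df2) == (1, n - 4)

    def test_null_instrument_mean_f_near_one(self, rng):
        # permuted instrument: F should behave like F(1, n-k), mean ~ 1
        n = 800
        strata = rng.choice(["a", "b"], size=n)
        t = (rng.random(n) < 0.3).astype(float)
        z = rng.random(n) < 0.5
        fs = []
        for _ in range(300):
            zp = rng.permutation(z)
            fs.append(first_stage_f(strata, zp, t)[0])
        fs = np.array(fs)
        m = (n - 3) / (n - 5)  # mean of F(1, n-k)
        assert abs(fs.mean() - m) < 3 * fs.std(ddof=1) / np.sqrt(len(fs))

    def test_expected_f_monotone_in_rate_gap(self, rng):
        means = []
        for gap in (0.05, 0.15, 0.30):
            vals = []
            for _ in range(60):
                n = 1500
                z = rng.random(n) < 0.5
                t = (rng.random(n) < 0.25 + gap * z).astype(float)
                vals.append(first_stage_f(np.repeat("s", n), z, t)[0])
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestWeightedPearson:
    def test_perfect_correlations(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        w = np.array([3.0, 1.0, 7.0, 2.0])
        assert weighted_pearson(x, x, w) == pytest.approx(1.0)
        assert weighted_pearson(x, x[::-1], w) == pytest.approx(-1.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_equal_weights_reduce_to_pearson(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 30))
        x = rng.random(n)
        y = rng.random(n) + 0.5 * x
        r = weighted_pearson(x, y, np.full(n, 2.5))
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            weighted_pearson([1, 1, 1], [1, 2, 3], [1, 1, 1])
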