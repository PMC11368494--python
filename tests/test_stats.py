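import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from migtrack import stats
from migtrack.stats import (SeparationError, aicc_value, all_subsets_average,
                            anova_f, characteristics_table, encode_region,
                            logistic_fit, mann_whitney_u, pearson_screen,
                            pooled_rate_pct, standardize)


class TestStandardize:
    def test_unit_scale(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [10.0, 10.0, 30.0, 30.0]})
        out = standardize(df)
        assert abs(out["a"].mean()) < 1e-10
        assert out["a"].std(ddof=1) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            standardize(pd.DataFrame({"a": [1.0, 1.0, 1.0]}))

    def test_region_encoding_reference_dropped(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0],
                           "winter_region": ["MAV", "Chenier", "Other"]})
        out = encode_region(df)
        assert "winter_region_MAV" not in out.columns
        assert set(c for c in out.columns if c.startswith("winter_region")) == \
            {"winter_region_Chenier", "winter_region_Other"}


class TestPearsonScreen:
    def test_self_correlation(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"x": x, "y": x.copy(), "z": -x})
        scr = pearson_screen(df, threshold=0.99)
        assert scr.table.loc["x", "y"] == pytest.approx(1.0)
        assert scr.table.loc["x", "z"] == pytest.approx(-1.0)
        assert ("x", "y", 1.0) in [(a, b, round(r, 6)) for a, b, r in scr.flagged]

    def test_priority_order_drops_later_member(self):
        x = np.arange(20.0)
        df = pd.DataFrame({"duration": x, "arrival": x + 0.01})
        scr = pearson_screen(df, threshold=0.6,
                             priority=["duration", "arrival"])
        assert scr.excluded == ["arrival"]

    def test_simulated_r08_recovered(self):
        hits = 0
        for s in range(50):
            rng = np.random.default_rng(s)
            x = rng.normal(size=500)
            y = 0.8 * x + np.sqrt(1 - 0.64) * rng.normal(size=500)
            scr = pearson_screen(pd.DataFrame({"x": x, "y": y}), threshold=0.95)
            if 0.75 <= scr.table.loc["x", "y"] <= 0.85:
                hits += 1
        assert hits / 50 >= 0.90

    def test_zero_variance_column_flagged(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        scr = pearson_screen(df)
        assert scr.zero_variance == ["c"]
        assert "c" not in scr.table.columns


class TestLogisticFit:
    def test_null_model_intercept_closed_form(self):
        y = np.array([1] * 31 + [0] * 25)
        fit = logistic_fit(y, pd.DataFrame(index=range(56)))
        assert fit.coef["const"] == pytest.approx(np.log(31 / 25), abs=1e-6)

    def test_matches_direct_likelihood_oracle(self):
        """IRLS coefficients equal an independent optimizer's on random
        small problems (1e-6)."""
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            n, k = 80, 2
            X = rng.normal(size=(n, k))
            beta = rng.normal(0, 1, k + 1)
            p = 1 / (1 + np.exp(-(beta[0] + X @ beta[1:])))
            y = (rng.random(n) < p).astype(float)
            if len(np.unique(y)) < 2:
                continue
            Xdf = pd.DataFrame(X, columns=["a", "b"])
            fit = logistic_fit(y, Xdf)

            def nll(b):
                eta = b[0] + X @ b[1:]
                return np.sum(np.log1p(np.exp(eta)) - y * eta)

            res = minimize(nll, np.zeros(k + 1), method="BFGS",
                           options={"gtol": 1e-12})
            np.testing.assert_allclose(fit.coef.to_numpy(), res.x, atol=1e-5)

    def test_perfect_separation_flagged(self):
        X = pd.DataFrame({"x": np.r_[np.full(10, -1.0), np.full(10, 1.0)]
                          + np.linspace(0, .01, 20)})
        y = np.r_[np.zeros(10), np.ones(10)]
        fit = logistic_fit(y, X)
        assert fit.separated

    def test_aicc_reduces_to_aic_for_large_n(self):
        ll, k = -100.0, 3
        aic = -2 * ll + 2 * k
        assert abs(aicc_value(ll, k, 10 ** 5) - aic) < 0.01


class TestModelAveraging:
    def _data(self, seed=0, beta=2.0, n=300):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(0.2 + beta * x)))
        y = (rng.random(n) < p).astype(float)
        return y, pd.DataFrame({"x": x, "z": z})

    def test_two_model_weights_closed_form(self):
        y, X = self._data(seed=1)
        ma = all_subsets_average(y, X[["x"]], delta_max=1e9)
        f0 = logistic_fit(y, X[[]])
        f1 = logistic_fit(y, X[["x"]])
        d = np.array([f.aicc for f in (f0, f1)])
        w = np.exp(-0.5 * (d - d.min()))
        w /= w.sum()
        got = ma.models.set_index("terms")["weight"]
        assert got["(null)"] == pytest.approx(w[0], abs=1e-10)
        assert got["x"] == pytest.approx(w[1], abs=1e-10)

    def test_duplicate_predictors_symmetric(self):
        y, X = self._data(seed=2)
        X2 = pd.DataFrame({"x1": X["x"], "x2": X["x"]})
        ma = all_subsets_average(y, X2, delta_max=1e9)
        assert ma.coef["x1"] == pytest.approx(ma.coef["x2"], rel=1e-6)

    def test_strong_effect_sign_and_ci(self):
        hits = 0
        n_rep = 40
        for s in range(n_rep):
            y, X = self._data(seed=200 + s)
            ma = all_subsets_average(y, X)
            if ma.coef["x"] > 0 and ma.ci_low["x"] > 0:
                hits += 1
        assert hits / n_rep >= 0.95

    def test_single_retained_model_equals_fit(self):
        y, X = self._data(seed=3)
        ma = all_subsets_average(y, X[["x"]], delta_max=1e-12)
        kept = ma.models.iloc[0]
        fit = (logistic_fit(y, X[["x"]]) if kept["terms"] == "x"
               else logistic_fit(y, X[[]]))
        assert ma.coef["const"] == pytest.approx(fit.coef["const"], abs=1e-10)

    def test_enumeration_refused_above_12(self):
        y, X = self._data(seed=4)
        X13 = pd.concat([X["x"]] * 13, axis=1)
        X13.columns = [f"c{i}" for i in range(13)]
        with pytest.raises(ValueError, match="12"):
            all_subsets_average(y, X13)


class TestGroupTests:
    def test_identical_samples_p_one(self):
        u, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_disjoint_samples_exact_p(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_large_shift_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 80)
        b = rng.normal(3, 1, 80)
        _, p = mann_whitney_u(a, b)
        assert p < 0.001

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 25)
        b = rng.normal(1, 1, 30)
        u1, p1 = mann_whitney_u(a, b)
        u2, p2 = mann_whitney_u(np.exp(a), np.exp(b))
        assert u1 == u2 and p1 == pytest.approx(p2)

    def test_anova_equal_means_f_near_zero(self):
        g = [np.array([1.0, 2.0, 3.0]), np.array([3.0, 2.0, 1.0])]
        F, df1, df2, p = anova_f(g)
        assert F == pytest.approx(0.0, abs=1e-12)
        assert (df1, df2) == (1, 4)
        assert p == pytest.approx(1.0)

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.7, 1, 20)
        F, _, _, _ = anova_f([a, b])
        from scipy.stats import ttest_ind
        t, _ = ttest_ind(a, b)
        assert F == pytest.approx(t ** 2, rel=1e-10)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_f([np.array([1.0, 1.0]), np.array([2.0, 2.0])])


class TestCharacteristicsTable:
    class S:
        def __init__(self, region, d):
            self.winter_region = region
            self.total_distance_km = d
            self.duration_days = d / 50
            self.n_stopovers = 10
            self.n_reverse = 1

    def test_mean_and_se(self):
        t = characteristics_table([self.S("A", 4.0), self.S("A", 6.0)])
        row = t.set_index("region").loc["A"]
        assert row["total_distance_km_mean"] == pytest.approx(5.0)
        assert row["total_distance_km_se"] == pytest.approx(1.0)

    def test_single_individual_se_absent(self):
        t = characteristics_table([self.S("A", 4.0)])
        assert np.isnan(t.iloc[0]["total_distance_km_se"])

    def test_planted_region_means_recovered(self):
        rng = np.random.default_rng(3)
        planted = {"A": 5000.0, "B": 5600.0}
        rows = [self.S(r, rng.normal(m, 100))
                for r, m in planted.items() for _ in range(40)]
        t = characteristics_table(rows).set_index("region")
        for r, m in planted.items():
            se = t.loc[r, "total_distance_km_se"]
            assert abs(t.loc[r, "total_distance_km_mean"] - m) < 2 * se * 2


class TestPooledRate:
    def test_recovers_overall_percent(self):
        assert pooled_rate_pct([10, 30], [50.0, 100.0]) == pytest.approx(87.5)
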