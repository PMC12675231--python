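import numpy as np
import pandas as pd
import pytest

from oxyphen.association_models import (
    backward_eliminate,
    fit_ols_hc3,
    pca_scores,
    standardized_betas,
    vif,
)


class TestFitOlsHc3:
    def test_exact_linear_fit(self):
        x = np.arange(10.0)
        y = 2.0 + 3.0 * x
        fit = fit_ols_hc3(y, pd.DataFrame({"x": x}))
        assert fit.r2 == pytest.approx(1.0)
        assert fit.table.loc["x", "B"] == pytest.approx(3.0)
        assert fit.table.loc["x", "se_hc3"] == pytest.approx(0.0, abs=1e-8)

    def test_hand_sandwich_on_six_points(self):
        # HC3 sandwich computed by direct matrix arithmetic (frozen oracle)
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([1.2, 1.9, 3.3, 3.8, 5.4, 5.9])
        fit = fit_ols_hc3(y, pd.DataFrame({"x": x}))
        assert fit.table.loc["const", "B"] == pytest.approx(0.13333333, abs=1e-7)
        assert fit.table.loc["x", "B"] == pytest.approx(0.98571429, abs=1e-7)
        assert fit.table.loc["const", "se_hc3"] == pytest.approx(0.22617694, abs=1e-7)
        assert fit.table.loc["x", "se_hc3"] == pytest.approx(0.07076919, abs=1e-7)

    def test_hc3_close_to_classical_under_homoskedasticity(self, rng):
        import statsmodels.api as sm

        n = 5000
        x = rng.normal(size=n)
        y = 1.0 + 0.5 * x + rng.normal(size=n)
        fit = fit_ols_hc3(y, pd.DataFrame({"x": x}))
        classical = sm.OLS(y, sm.add_constant(x)).fit().bse[1]
        assert 0.95 < fit.table.loc["x", "se_hc3"] / classical < 1.05

    def test_ci_contains_point_estimate(self, rng):
        x = rng.normal(size=80)
        y = x + rng.normal(size=80)
        fit = fit_ols_hc3(y, pd.DataFrame({"x": x}))
        t = fit.table
        assert ((t["ci_lo"] <= t["B"]) & (t["B"] <= t["ci_hi"])).all()
        assert fit.adj_r2 <= fit.r2

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.normal(size=30)})
        with pytest.raises(ValueError, match="rank deficient"):
            fit_ols_hc3(rng.normal(size=30), X)


class TestBackwardElimination:
    def test_strong_predictor_retained(self, rng):
        x = rng.normal(size=100)
        y = 2 * x + rng.normal(0, 0.5, 100)
        fit, trace = backward_eliminate(y, pd.DataFrame({"x": x}))
        assert trace.final_predictors == ["x"]
        assert trace.steps == []

    def test_noise_predictor_usually_dropped(self, rng):
        dropped = 0
        n_sim = 200
        for _ in range(n_sim):
            x = rng.normal(size=120)
            noise = rng.normal(size=120)
            y = 2 * x + rng.normal(0, 1, 120)
            _, trace = backward_eliminate(y, pd.DataFrame({"x": x, "noise": noise}))
            dropped += "noise" not in trace.final_predictors
        assert dropped >= 0.85 * n_sim

    def test_all_noise_can_reduce_to_intercept(self, rng):
        y = rng.normal(size=60)
        X = pd.DataFrame({"a": rng.normal(size=60), "b": rng.normal(size=60)})
        fit, trace = backward_eliminate(y, X, threshold=1e-6)
        assert trace.final_predictors == []
        assert list(fit.table.index) == ["const"]

    def test_order_invariance_with_distinct_pvalues(self, rng):
        x1 = rng.normal(size=150)
        x2 = rng.normal(size=150)
        x3 = rng.normal(size=150)
        y = 1.5 * x1 + 0.3 * x2 + rng.normal(size=150)
        X = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
        _, t_fwd = backward_eliminate(y, X)
        _, t_rev = backward_eliminate(y, X[["x3", "x2", "x1"]])
        assert set(t_fwd.final_predictors) == set(t_rev.final_predictors)

    def test_dropped_ps_above_threshold(self, rng):
        X = pd.DataFrame(rng.normal(size=(80, 4)), columns=list("abcd"))
        y = 2 * X["a"].to_numpy() + rng.normal(size=80)
        _, trace = backward_eliminate(y, X)
        assert all(p > 0.10 for _, p in trace.steps)


class TestVif:
    def test_orthogonal_columns_unit_vif(self):
        X = pd.DataFrame({"a": [1, -1, 1, -1.0], "b": [1, 1, -1, -1.0]})
        assert vif(X).max() == pytest.approx(1.0)

    def test_duplicate_column_infinite(self, rng):
        x = rng.normal(size=20)
        out = vif(pd.DataFrame({"a": x, "b": x}))
        assert np.isinf(out).all()

    def test_closed_form_from_empirical_correlation(self, rng):
        a = rng.normal(size=4000)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.normal(size=4000)
        out = vif(pd.DataFrame({"a": a, "b": b}))
        r = np.corrcoef(a, b)[0, 1]
        assert out["a"] == pytest.approx(1 / (1 - r**2), rel=1e-9)
        assert out["a"] == pytest.approx(1 / (1 - 0.81), rel=0.1)


class TestPca:
    def test_perfectly_correlated_pair(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1})
        res = pca_scores(df, ["a", "b"], k=1)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_sign_convention_restored_under_global_flip(self, rng):
        df = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        df["b"] = df["a"] + 0.3 * df["b"]
        df["c"] = df["a"] + 0.3 * df["c"]
        res = pca_scores(df, list("abc"), k=1)
        res_flipped = pca_scores(-df, list("abc"), k=1)
        assert np.allclose(res.scores[:, 0], -res_flipped.scores[:, 0], atol=1e-8)
        # both orientations correlate positively with their input means
        z = (df - df.mean()) / df.std(ddof=1)
        assert np.corrcoef(res.scores[:, 0], z.mean(axis=1))[0, 1] > 0

    def test_independent_variables_share_variance(self, rng):
        df = pd.DataFrame(rng.normal(size=(8000, 4)), columns=list("abcd"))
        res = pca_scores(df, list("abcd"), k=4)
        assert np.all(np.diff(res.explained_variance_ratio) <= 1e-12)
        assert res.explained_variance_ratio == pytest.approx([0.25] * 4, abs=0.03)

    def test_k_too_large(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        with pytest.raises(ValueError):
            pca_scores(df, ["a", "b"], k=3)


class TestStandardizedBetas:
    def test_simple_regression_equals_pearson_r(self, rng):
        x = rng.normal(size=200)
        y = 0.7 * x + rng.normal(size=200)
        fit = fit_ols_hc3(y, pd.DataFrame({"x": x}))
        r = np.corrcoef(x, y)[0, 1]
        assert standardized_betas(fit)["x"] == pytest.approx(r, rel=1e-9)

    def test_matches_zscored_refit(self, rng):
        X = pd.DataFrame(rng.normal(size=(120, 3)), columns=list("abc"))
        y = X["a"].to_numpy() - 2 * X["b"].to_numpy() + rng.normal(size=120)
        fit = fit_ols_hc3(y, X)
        Z = (X - X.mean()) / X.std(ddof=1)
        yz = (y - y.mean()) / y.std(ddof=1)
        refit = fit_ols_hc3(yz, Z)
        for c in "abc":
            assert standardized_betas(fit)[c] == pytest.approx(
                refit.table.loc[c, "B"], rel=1e-9
            )
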