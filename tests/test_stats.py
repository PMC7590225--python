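"""Statistical battery: brute-force oracles, gates, and report shapes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from greenspace.stats import (
    ADJUSTMENT_COVARIATES,
    boundary_grid,
    buffer_grid,
    classify_bmi,
    health_models,
    levene,
    ols,
    pearson_matrix,
    stars,
    t_from_summary,
    two_sample_t,
    urban_rural_compare,
)


class TestBMI:
    @pytest.mark.parametrize(
        "bmi,category",
        [
            (15.0, "underweight"),
            (18.5, "normal"),
            (24.0, "normal"),
            (25.0, "overweight"),
            (29.9, "overweight"),
            (30.0, "obese"),
            (45.0, "obese"),
        ],
    )
    def test_boundaries_lower_inclusive(self, bmi, category):
        assert classify_bmi(bmi) == category

    def test_nonpositive_rejected(self):
        for bad in (0.0, -3.0, float("nan")):
            with pytest.raises(ValueError):
                classify_bmi(bad)


class TestLevene:
    def test_identical_samples_give_zero(self):
        a = np.array([1.0, 4.0, 2.0, 8.0])
        w, p = levene(a, a.copy())
        assert w == 0.0

    def test_matches_absolute_deviation_anova_by_hand(self):
        a = np.array([1.0, 2.0, 6.0, 9.0])
        b = np.array([3.0, 3.5, 4.0, 4.5, 5.0])
        # hand computation: one-way ANOVA F on |x - group mean|
        za, zb = np.abs(a - a.mean()), np.abs(b - b.mean())
        k, n = 2, za.size + zb.size
        zbar = np.concatenate([za, zb]).mean()
        between = za.size * (za.mean() - zbar) ** 2 + zb.size * (zb.mean() - zbar) ** 2
        within = ((za - za.mean()) ** 2).sum() + ((zb - zb.mean()) ** 2).sum()
        expected = (n - k) / (k - 1) * between / within
        w, p = levene(a, b)
        assert w == pytest.approx(expected, rel=1e-12)
        # independent implementation: scipy's mean-centered variant
        w2, p2 = sps.levene(a, b, center="mean")
        assert w == pytest.approx(w2, rel=1e-12)
        assert p == pytest.approx(p2, rel=1e-12)

    def test_detects_variance_ratio_with_power(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            a = rng.normal(0, 1, 200)
            b = rng.normal(0, 5, 200)
            _, p = levene(a, b)
            hits += p < 0.01
        assert hits >= 38  # >= 95 % of replicates

    def test_degenerate_flat_samples(self):
        w, p = levene([2.0, 2.0, 2.0], [2.0, 2.0])
        assert (w, p) == (0.0, 1.0)


class TestTwoSampleT:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = two_sample_t(a, a.copy(), method="pooled")
        assert res.t == 0.0 and res.p == 1.0

    def test_pooled_equals_welch_for_equal_n_equal_var(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 2, 15)
        b = a + 1.0  # same variance exactly, equal n
        rp = two_sample_t(a, b, method="pooled")
        rw = two_sample_t(a, b, method="welch")
        assert rp.t == pytest.approx(rw.t, rel=1e-12)
        assert rp.df == pytest.approx(rw.df, rel=1e-12)

    def test_matches_textbook_formula_and_scipy(self):
        rng = np.random.default_rng(2)
        a = rng.normal(10, 2, 10)
        b = rng.normal(12, 4, 10)
        for method, equal_var in (("pooled", True), ("welch", False)):
            res = two_sample_t(a, b, method=method)
            # brute-force textbook computation
            s1, s2 = a.var(ddof=1), b.var(ddof=1)
            if method == "pooled":
                sp2 = ((a.size - 1) * s1 + (b.size - 1) * s2) / (a.size + b.size - 2)
                se = np.sqrt(sp2 * (1 / a.size + 1 / b.size))
                df = a.size + b.size - 2
            else:
                se = np.sqrt(s1 / a.size + s2 / b.size)
                df = (s1 / a.size + s2 / b.size) ** 2 / (
                    (s1 / a.size) ** 2 / (a.size - 1)
                    + (s2 / b.size) ** 2 / (b.size - 1)
                )
            assert res.t == pytest.approx((a.mean() - b.mean()) / se, abs=1e-12)
            assert res.df == pytest.approx(df, abs=1e-12)
            scipy_res = sps.ttest_ind(a, b, equal_var=equal_var)
            assert res.t == pytest.approx(scipy_res.statistic, rel=1e-12)
            assert res.p == pytest.approx(scipy_res.pvalue, rel=1e-12)

    def test_welch_df_bounds(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a = rng.normal(0, rng.uniform(0.5, 5), rng.integers(3, 30))
            b = rng.normal(0, rng.uniform(0.5, 5), rng.integers(3, 30))
            res = two_sample_t(a, b, method="welch")
            assert min(a.size, b.size) - 1 <= res.df <= a.size + b.size - 2 + 1e-9

    def test_auto_gate_uses_levene(self):
        rng = np.random.default_rng(4)
        same = two_sample_t(rng.normal(0, 1, 100), rng.normal(1, 1, 100))
        diff = two_sample_t(rng.normal(0, 1, 100), rng.normal(1, 10, 100))
        assert same.method == "pooled"
        assert diff.method == "welch"


class TestTFromSummary:
    def test_published_elderly_row_pooled(self):
        res = t_from_summary(17.19, 2.82, 20, 22.66, 3.37, 74, "pooled")
        assert res.se_diff == pytest.approx(0.82, abs=0.005)
        assert res.t == pytest.approx(-6.65, abs=0.01)

    def test_published_white_row_welch(self):
        res = t_from_summary(79.53, 7.97, 20, 95.88, 4.2, 74, "welch")
        assert res.se_diff == pytest.approx(1.85, abs=0.005)

    def test_equal_means_give_zero_t(self):
        for method in ("pooled", "welch"):
            assert t_from_summary(5, 1.0, 10, 5, 2.0, 12, method).t == 0.0

    def test_summary_matches_raw_sample_test(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(3, 1, 14), rng.normal(4, 2, 18)
        raw = two_sample_t(a, b, method="pooled")
        summ = t_from_summary(
            a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size, "pooled"
        )
        assert summ.t == pytest.approx(raw.t, abs=1e-12)
        assert summ.se_diff == pytest.approx(raw.se_diff, abs=1e-12)
        assert summ.p == pytest.approx(raw.p, abs=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            t_from_summary(1, 0.0, 10, 2, 1.0, 10, "pooled")
        with pytest.raises(ValueError):
            t_from_summary(1, 1.0, 10, 2, 1.0, 10, "auto")


class TestPearson:
    def test_self_and_affine_correlation(self):
        x = pd.Series(np.arange(10.0))
        wide = pd.DataFrame({"county_id": range(10), "a": x, "b": 2 * x + 1})
        corr = pearson_matrix(wide)
        assert corr.loc["a", "a"] == pytest.approx(1.0)
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(6)
        data = pd.DataFrame(rng.normal(size=(20, 12)), columns=[f"c{i}" for i in range(12)])
        data.insert(0, "county_id", range(20))
        corr = pearson_matrix(data)
        x = data.drop(columns="county_id").to_numpy()
        xc = x - x.mean(axis=0)
        cov = xc.T @ xc
        brute = cov / np.sqrt(np.outer(np.diag(cov), np.diag(cov)))
        assert np.allclose(corr.to_numpy(), brute, atol=1e-12)

    def test_zero_variance_column_flagged_missing(self):
        wide = pd.DataFrame(
            {"county_id": range(5), "a": [1.0, 2, 3, 4, 5], "flat": [7.0] * 5}
        )
        corr = pearson_matrix(wide)
        assert np.isnan(corr.loc["a", "flat"])


class TestOLS:
    def test_exact_linear_fit(self):
        x = pd.DataFrame({"x": np.arange(10.0)})
        y = 3.0 * x["x"] + 2.0
        fit = ols(y, x)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.coefficients.set_index("predictor").loc["x", "B"] == pytest.approx(3.0)

    def test_matches_pseudoinverse_oracle(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        y = rng.normal(size=50)
        fit = ols(y, X)
        design = np.column_stack([np.ones(50), X.to_numpy()])
        expected = np.linalg.pinv(design) @ y
        assert np.allclose(fit.coefficients["B"].to_numpy(), expected, atol=1e-10)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = X["a"] * 2 - X["b"] + rng.normal(size=40)
        fit = ols(y, X)
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        assert np.allclose(fit.coefficients["B"].to_numpy(), ref.params.to_numpy(), atol=1e-10)
        assert np.allclose(fit.coefficients["SE"].to_numpy(), ref.bse.to_numpy(), atol=1e-10)
        assert fit.r2 == pytest.approx(ref.rsquared, abs=1e-12)
        assert fit.adj_r2 == pytest.approx(ref.rsquared_adj, abs=1e-12)
        assert fit.f_stat == pytest.approx(ref.fvalue, rel=1e-10)

    def test_standardized_beta_identity_and_affine_invariance(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["u", "v"])
        y = pd.Series(X["u"] - 2 * X["v"] + rng.normal(size=30))
        fit = ols(y, X)
        coef = fit.coefficients.set_index("predictor")
        for name in ("u", "v"):
            expected = coef.loc[name, "B"] * X[name].std(ddof=1) / y.std(ddof=1)
            assert coef.loc[name, "beta"] == pytest.approx(expected, rel=1e-12)
        # rescaling a predictor leaves beta unchanged, scales B inversely
        X2 = X.assign(u=X["u"] * 10)
        fit2 = ols(y, X2)
        coef2 = fit2.coefficients.set_index("predictor")
        assert coef2.loc["u", "beta"] == pytest.approx(coef.loc["u", "beta"], rel=1e-10)
        assert coef2.loc["u", "B"] == pytest.approx(coef.loc["u", "B"] / 10, rel=1e-10)

    def test_irrelevant_predictor_raises_r2_lowers_adj(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame({"x": rng.normal(size=25)})
        y = 2 * X["x"] + rng.normal(size=25)
        fit1 = ols(y, X)
        fit2 = ols(y, X.assign(noise=rng.normal(size=25)))
        assert fit2.r2 >= fit1.r2 - 1e-12

    def test_rank_deficiency_names_offenders(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame({"a": rng.normal(size=20)})
        X["twice_a"] = 2 * X["a"]
        with pytest.raises(ValueError, match="twice_a"):
            ols(rng.normal(size=20), X)

    def test_listwise_deletion_reports_n(self):
        X = pd.DataFrame({"x": [1.0, 2, 3, 4, 5, np.nan, 7, 8]})
        y = pd.Series([2.0, 4, 6, 8, 10, 12, 14, np.nan]).to_numpy()
        fit = ols(y, X)
        assert fit.n == 6


class TestReportShapes:
    def test_urban_rural_compare_rows_and_gate(self, small_health, small_exposure):
        from greenspace.exposure import exposure_wide

        table, _ = small_health
        wide = exposure_wide(small_exposure[small_exposure["buffer_m"] == 0])
        merged = table.merge(wide, on="county_id", how="left")
        report = urban_rural_compare(merged)
        expected_vars = {
            c for c in merged.columns if c not in ("county_id", "urban")
        }
        assert set(report["variable"]) == expected_vars
        assert set(report["method"]) <= {"pooled", "welch"}

    def test_constant_variable_gives_p_one(self, small_health):
        table, _ = small_health
        t = table.copy()
        t["flat"] = 42.0
        report = urban_rural_compare(t, variables=["flat"])
        assert report.loc[0, "t"] == 0.0
        assert report.loc[0, "p"] == 1.0

    def test_boundary_grid_has_24_cells(self, small_health, small_exposure):
        table, _ = small_health
        grid = boundary_grid(table, small_exposure)
        assert len(grid) == 24
        assert set(grid["model"]) == {"null", "adjusted"}
        # null and adjusted models keep the same greenspace sign for the
        # planted TIN/combined cell on this world
        cell = grid.query("scheme == 'combined' and metric == 'TIN'")
        assert len(cell) == 2

    def test_buffer_grid_shape(self, small_health, small_exposure):
        table, _ = small_health
        out = buffer_grid(table, small_exposure)
        assert len(out["coefficients"]) == 11 * 4
        assert list(out["model"]["buffer_m"]) == [0, 300, 500, 1000]

    def test_health_models_match_buffer_zero_column(self, small_health, small_exposure):
        table, _ = small_health
        hm = health_models(table, small_exposure)
        bg = buffer_grid(table, small_exposure)
        ex_hm = hm["coefficients"].query("outcome == 'exercise'").set_index("predictor")["B"]
        ex_bg = (
            bg["coefficients"].query("buffer_m == 0").set_index("predictor")["B"]
        )
        assert np.allclose(ex_hm.to_numpy(), ex_bg[ex_hm.index].to_numpy(), atol=1e-12)
        assert set(hm["model"]["outcome"]) == {
            "exercise", "physical_health", "mental_health",
        }

    def test_star_thresholds(self):
        assert stars(0.0005) == "***"
        assert stars(0.005) == "**"
        assert stars(0.04) == "*"
        assert stars(0.06) == ""
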