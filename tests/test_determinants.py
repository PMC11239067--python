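"""Standardization, OLS inference, GVIF, group tests, SVI residual slope."""

import numpy as np
import pandas as pd
import pytest

from treegrowth.determinants import (
    ModelSpec,
    compact_letter_display,
    fit_ols,
    group_compare,
    gvif,
    pearson_screen,
    residuals_vs_svi,
    standardize_2sd,
)


class TestStandardize:
    def test_mean_zero_sd_half(self, rng):
        z = standardize_2sd(rng.normal(5, 3, 1000))
        assert np.mean(z) == pytest.approx(0.0, abs=1e-12)
        assert np.std(z, ddof=1) == pytest.approx(0.5)

    def test_hand_computed_example(self):
        assert standardize_2sd([0, 0, 2, 2]) == pytest.approx(
            [-0.433, -0.433, 0.433, 0.433], abs=5e-4
        )

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError):
            standardize_2sd([3.0, 3.0, 3.0])

    def test_linear_and_order_preserving(self, rng):
        x = rng.normal(size=50)
        z = standardize_2sd(x)
        assert np.all(np.diff(z[np.argsort(x)]) >= 0)


def _minimal_frame(n, rng, beta_dbh=-0.1, noise=0.0):
    species = rng.choice(["Ginkgo", "Pin Oak", "other"], size=n)
    dbh = rng.uniform(1, 40, n)
    y = 0.3 + beta_dbh * standardize_2sd(dbh) + noise * rng.normal(size=n)
    return pd.DataFrame(
        {"rate_in_per_yr": y, "species_norm": species, "dbh_in_05": dbh}
    )


SIMPLE_SPEC = ModelSpec(categorical={}, continuous=("dbh_in_05",), include_borough=False)


class TestFitOLS:
    def test_noise_free_coefficients_recovered(self, rng):
        data = _minimal_frame(500, rng)
        fit = fit_ols(SIMPLE_SPEC, data)
        est = fit.table.set_index("term")["estimate"]
        assert est["const"] == pytest.approx(0.3, abs=1e-8)
        assert est["dbh_in_05"] == pytest.approx(-0.1, abs=1e-8)
        assert fit.rmse == pytest.approx(0.0, abs=1e-8)

    def test_residuals_sum_to_zero(self, rng):
        data = _minimal_frame(200, rng, noise=0.2)
        fit = fit_ols(SIMPLE_SPEC, data)
        assert fit.residuals.sum() == pytest.approx(0.0, abs=1e-8)

    def test_ci_coverage_monte_carlo(self, rng):
        hits = 0
        reps = 200
        for _ in range(reps):
            x = rng.normal(size=400)
            y = 1.0 + 0.5 * x + rng.normal(size=400)
            df = pd.DataFrame(
                {"rate_in_per_yr": y, "species_norm": "other", "dbh_in_05": x}
            )
            fit = fit_ols(SIMPLE_SPEC, df)
            row = fit.table.set_index("term").loc["dbh_in_05"]
            # slope on the 2-SD standardized scale
            true = 0.5 * 2 * np.std(x, ddof=1)
            hits += row["ci_low"] <= true <= row["ci_high"]
        assert 0.90 <= hits / reps <= 0.99

    def test_rank_deficiency_reported(self, rng):
        data = _minimal_frame(100, rng)
        data["copy"] = data["dbh_in_05"]
        spec = ModelSpec(
            categorical={}, continuous=("dbh_in_05", "copy"), include_borough=False
        )
        with pytest.raises(ValueError, match="rank deficient|collinear"):
            fit_ols(spec, data)

    def test_row_order_invariance(self, rng):
        data = _minimal_frame(300, rng, noise=0.1)
        fit1 = fit_ols(SIMPLE_SPEC, data)
        fit2 = fit_ols(SIMPLE_SPEC, data.sample(frac=1.0, random_state=1))
        a = fit1.table.set_index("term")["estimate"]
        b = fit2.table.set_index("term")["estimate"]
        assert np.allclose(a.sort_index(), b.sort_index())


class TestGVIF:
    def test_orthogonal_columns_give_one(self):
        n = 64
        X = pd.DataFrame(
            {
                "const": 1.0,
                "a": np.tile([1.0, -1.0], n // 2),
                "b": np.repeat([1.0, -1.0], n // 2),
            }
        )
        out = gvif(X, {"a": ["a"], "b": ["b"]})
        assert np.allclose(out["gvif"], 1.0)

    def test_correlated_pair_closed_form(self, rng):
        x = rng.normal(size=5000)
        y = 0.8 * x + np.sqrt(1 - 0.64) * rng.normal(size=5000)
        X = pd.DataFrame({"const": 1.0, "x": x, "y": y})
        out = gvif(X, {"x": ["x"], "y": ["y"]}).set_index("term")
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert out.loc["x", "gvif"] == pytest.approx(1 / (1 - r2), rel=1e-6)

    def test_single_column_terms_equal_classical_vif(self, rng):
        # GVIF of a 1-column term == 1/(1 - R^2) of that column on the rest
        X = pd.DataFrame(rng.normal(size=(500, 4)), columns=list("abcd"))
        X["b"] += 0.5 * X["a"]
        X["d"] += 0.3 * X["a"] - 0.4 * X["c"]
        Xc = X.copy()
        Xc.insert(0, "const", 1.0)
        out = gvif(Xc, {c: [c] for c in "abcd"}).set_index("term")
        for col in "abcd":
            others = [c for c in "abcd" if c != col]
            import statsmodels.api as sm

            r2 = sm.OLS(X[col], sm.add_constant(X[others])).fit().rsquared
            assert out.loc[col, "gvif"] == pytest.approx(1 / (1 - r2), rel=1e-6)


class TestCompactLetters:
    def test_no_differences_one_letter(self):
        letters = compact_letter_display(["a", "b", "c"], [])
        assert len(set(letters.values())) == 1

    def test_all_different_three_letters(self):
        letters = compact_letter_display(
            ["x", "y", "z"], [("x", "y"), ("x", "z"), ("y", "z")]
        )
        assert sorted(letters.values()) == ["a", "b", "c"]

    def test_chain_structure_shares_middle(self):
        # x differs from z; y differs from neither
        letters = compact_letter_display(["x", "y", "z"], [("x", "z")])
        assert set(letters["x"]) & set(letters["y"])
        assert set(letters["y"]) & set(letters["z"])
        assert not set(letters["x"]) & set(letters["z"])
        assert all(letters.values())


class TestGroupCompare:
    def test_identical_groups_share_letter(self, rng):
        df = pd.DataFrame(
            {
                "f": np.repeat(["a", "b", "c"], 30),
                "rate_in_per_yr": np.tile(rng.normal(0.3, 0.01, 30), 3),
            }
        )
        out = group_compare(df, "f")
        assert len(set(out.table["letters"])) == 1

    def test_separated_means_all_differ(self, rng):
        df = pd.DataFrame(
            {
                "f": np.repeat(["a", "b", "c"], 30),
                "rate_in_per_yr": np.concatenate(
                    [rng.normal(m, 0.01, 30) for m in (0.0, 10.0, 20.0)]
                ),
            }
        )
        out = group_compare(df, "f")
        assert sorted(out.table["letters"]) == ["a", "b", "c"]
        assert out.test == "anova+tukey"

    def test_two_group_null_rejection_rate_near_alpha(self, rng):
        rejections = 0
        reps = 1000
        for _ in range(reps):
            df = pd.DataFrame(
                {
                    "f": np.repeat(["a", "b"], 25),
                    "rate_in_per_yr": rng.normal(size=50),
                }
            )
            out = group_compare(df, "f")
            rejections += out.p_overall < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_thin_level_excluded_with_warning(self, rng):
        df = pd.DataFrame(
            {
                "f": ["a"] * 20 + ["b"] * 20 + ["c"],
                "rate_in_per_yr": rng.normal(size=41),
            }
        )
        with pytest.warns(UserWarning, match="excluded"):
            out = group_compare(df, "f")
        assert set(out.table["level"]) == {"a", "b"}


class TestPearsonScreen:
    def test_perfect_negative(self):
        df = pd.DataFrame({"rate_in_per_yr": [3.0, 2.0, 1.0, 0.0], "x": [0, 1, 2, 3.0]})
        out = pearson_screen(df, covariates=("x",))
        assert out["r"].iloc[0] == pytest.approx(-1.0)

    def test_null_pairs_small_r(self, rng):
        df = pd.DataFrame(
            {"rate_in_per_yr": rng.normal(size=10000), "x": rng.normal(size=10000)}
        )
        out = pearson_screen(df, covariates=("x",))
        assert abs(out["r"].iloc[0]) < 0.05

    def test_size_dependent_growth_negative_r(self, clean_city):
        from treegrowth import pipeline

        res = pipeline.run_from_frames(
            clean_city.observe_census("early"), clean_city.observe_census("late")
        )
        data = res.growth[res.growth["qc_status"] == "retained"]
        out = pearson_screen(data, covariates=("dbh_in_05",))
        assert out["r"].iloc[0] < 0


class TestResidualsVsSVI:
    def test_single_zone_errors(self, rng):
        data = _minimal_frame(300, rng, noise=0.1)
        data["zip"] = "10001"
        data["svi"] = rng.uniform(0, 1, len(data))
        with pytest.raises(ValueError, match="zones"):
            residuals_vs_svi(SIMPLE_SPEC, data, min_n=10)

    def test_known_svi_effect_recovered(self, rng):
        n = 6000
        data = _minimal_frame(n, rng, noise=0.05)
        data["zip"] = rng.choice([f"1{i:04d}" for i in range(12)], size=n)
        zone_svi = {f"1{i:04d}": (i + 0.5) / 12 for i in range(12)}
        data["svi"] = data["zip"].map(zone_svi)
        data["rate_in_per_yr"] = data["rate_in_per_yr"] + 0.2 * data["svi"]
        out = residuals_vs_svi(SIMPLE_SPEC, data, min_n=50)
        assert out.slope == pytest.approx(0.2, abs=0.05)
        assert out.p_value < 0.01

    def test_svi_never_a_model_term(self):
        with pytest.raises(ValueError, match="SVI"):
            ModelSpec(categorical={}, continuous=("svi",))
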