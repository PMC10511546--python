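"""Delta computation and its bias screens: partial-correlation oracle,
age-adjusted sex model, screen bookkeeping, and null calibration."""

import numpy as np
import pandas as pd
import pytest

from brainage_msn.delta import (
    compute_delta,
    covariate_screen,
    delta_summary,
    partial_correlation,
    sex_bias_test,
)


class TestComputeDelta:
    def test_perfect_predictions_give_zero_delta(self):
        ages = np.array([7.0, 12.0, 15.0])
        t = compute_delta(ages, ages)
        assert np.all(t["delta"] == 0.0)
        assert delta_summary(t)["mean"] == 0.0

    def test_constant_offset(self):
        ages = np.array([8.0, 10.0, 13.0, 16.0])
        t = compute_delta(ages + 1.0, ages)
        np.testing.assert_allclose(t["delta"], 1.0)

    def test_age_bands(self):
        ages = np.array([8.0, 12.0, 15.0])
        t = compute_delta(ages, ages)
        assert list(t["age_band"]) == ["childhood", "early_adolescence", "middle_adolescence"]

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            compute_delta([1.0, 2.0], [1.0])

    def test_shrinkage_model_gives_negative_delta_age_correlation(self, rng):
        """A model that shrinks predictions towards the mean overestimates the
        young and underestimates the old: r(delta, age) < 0."""
        ages = rng.uniform(6.5, 16.9, 200)
        pred = ages.mean() + 0.4 * (ages - ages.mean()) + rng.normal(0, 1, 200)
        t = compute_delta(pred, ages)
        assert np.corrcoef(t["delta"], t["actual_age"])[0, 1] < 0


class TestPartialCorrelation:
    def test_residual_on_residual_oracle(self, rng):
        """The pairwise-correlation formula equals correlating OLS residuals."""
        x = rng.normal(size=20)
        c = rng.normal(size=20)
        y = 0.5 * c + rng.normal(size=20)

        def resid(v):
            A = np.column_stack([np.ones(20), c])
            return v - A @ np.linalg.lstsq(A, v, rcond=None)[0]

        oracle = np.corrcoef(resid(x), resid(y))[0, 1]
        r, _ = partial_correlation(x, y, c, method="pearson")
        assert abs(r - oracle) < 1e-10

    def test_independent_variables_give_near_zero_r(self, rng):
        x = rng.normal(size=5000)
        y = rng.normal(size=5000)
        c = rng.normal(size=5000)
        r, p = partial_correlation(x, y, c)
        assert abs(r) < 0.05

    def test_fully_explained_by_control(self, rng):
        c = rng.normal(size=50)
        x = rng.normal(size=50)
        r, _ = partial_correlation(x, c, c + 1e-12 * rng.normal(size=50))
        assert abs(r) < 1e-4

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x, y, c = rng.normal(size=(3, 40))
        y = y + 0.3 * c + 0.2 * x
        df = pd.DataFrame({"x": x, "y": y, "c": c})
        for method in ("pearson", "spearman"):
            r, p = partial_correlation(x, y, c, method=method)
            ref = pingouin.partial_corr(df, x="x", y="y", covar="c", method=method)
            assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
            assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_rescaling_control_leaves_r_unchanged(self, rng):
        x, y, c = rng.normal(size=(3, 30))
        r1, _ = partial_correlation(x, y, c)
        r2, _ = partial_correlation(x, y, 100.0 * c - 7.0)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_degenerate_inputs_error(self, rng):
        x = rng.normal(size=10)
        with pytest.raises(ValueError):
            partial_correlation(x, np.ones(10), rng.normal(size=10))
        with pytest.raises(ValueError):
            partial_correlation(x[:3], x[:3], x[:3])


class TestSexBias:
    def test_no_sex_effect_gives_small_statistic(self, rng):
        n = 400
        age = rng.uniform(6.5, 16.9, n)
        sex = np.where(rng.uniform(size=n) < 0.5, "M", "F")
        delta = -0.3 * (age - age.mean()) + rng.normal(0, 0.5, n)
        t, p = sex_bias_test(delta, sex, age)
        assert abs(t) < 3.0 and p > 0.001

    def test_injected_male_offset_recovered(self, rng):
        """+1 yr male delta offset at n=500 is recovered within 3 SE."""
        import statsmodels.api as sm
        n = 500
        age = rng.uniform(6.5, 16.9, n)
        sex = np.where(rng.uniform(size=n) < 0.6, "M", "F")
        delta = 1.0 * (sex == "M") - 0.2 * (age - 12) + rng.normal(0, 1.0, n)
        X = sm.add_constant(np.column_stack([(sex == "M").astype(float), age]))
        fit = sm.OLS(delta, X).fit()
        assert abs(fit.params[1] - 1.0) < 3 * fit.bse[1]
        t, p = sex_bias_test(delta, sex, age)
        assert p < 1e-6  # and the screen statistic flags it

    def test_age_confounded_sex_difference_not_flagged(self, rng):
        """Sex correlates with age and delta depends only on age: the
        age-adjusted model must not report a sex effect."""
        n = 2000
        age = rng.uniform(6.5, 16.9, n)
        p_male = np.clip(0.3 + 0.04 * (age - 6.5), 0, 1)
        sex = np.where(rng.uniform(size=n) < p_male, "M", "F")
        delta = -0.3 * (age - 12.0) + rng.normal(0, 0.5, n)
        t, p = sex_bias_test(delta, sex, age)
        assert p > 0.01

    def test_single_sex_errors(self, rng):
        with pytest.raises(ValueError):
            sex_bias_test(rng.normal(size=10), np.array(["M"] * 10), rng.uniform(6, 17, 10))


class TestScreen:
    def _delta_tables(self, rng, n_models=10, n=82, iq_missing=26):
        tables = {}
        for k in range(n_models):
            age = rng.uniform(6.5, 16.9, n)
            iq = rng.normal(110, 15, n)
            iq[rng.choice(n, iq_missing, replace=False)] = np.nan
            tables[f"model{k}"] = pd.DataFrame({
                "delta": rng.normal(0, 2, n),
                "actual_age": age,
                "efc": rng.normal(0.45, 0.05, n),
                "iq": iq,
                "sex": np.where(rng.uniform(size=n) < 0.7, "M", "F"),
            })
        return tables

    def test_bookkeeping_50_continuous_plus_10_sex_rows(self, rng):
        table, mean_r = covariate_screen(self._delta_tables(rng))
        continuous = table[table["method"].isin(["pearson", "spearman"])]
        sex_rows = table[table["method"] == "ols_t"]
        assert len(continuous) == 40  # 10 models x 2 covariates x 2 methods
        assert len(sex_rows) == 10
        assert len(table) == 50
        assert set(mean_r) == {"efc", "iq"}

    def test_iq_missingness_reduces_row_n(self, rng):
        table, _ = covariate_screen(self._delta_tables(rng, n=82, iq_missing=26))
        iq_rows = table[table["covariate"] == "iq"]
        assert (iq_rows["n"] == 56).all()
        efc_rows = table[table["covariate"] == "efc"]
        assert (efc_rows["n"] == 82).all()

    def test_null_efc_mean_r_near_zero(self, rng):
        """EFC independent of delta: the mean Pearson r across models stays
        within +/-0.1 of zero (averaged over 50 screen replicates at n=82)."""
        means = []
        for _ in range(50):
            _, mean_r = covariate_screen(self._delta_tables(rng, n_models=3))
            means.append(mean_r["efc"])
        assert abs(np.mean(means)) < 0.1

    def test_missing_covariate_column_errors(self, rng):
        tabs = self._delta_tables(rng, n_models=1)
        bad = {k: v.drop(columns=["efc"]) for k, v in tabs.items()}
        with pytest.raises(ValueError, match="efc"):
            covariate_screen(bad)
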