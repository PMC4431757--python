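"""Correlations, robust/OLS regression machinery and the five-model layout."""

import numpy as np
import pandas as pd
import pytest

import dearisk as d
from dearisk.inference import (
    _specs,
    comparison_table,
    pearson_correlation,
)
from dearisk.robust import RankDeficientError, RobustLinearModel


def _product_moment(x, y):
    xc = x - x.mean()
    yc = y - y.mean()
    return (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())


class TestPearson:
    def test_hand_example(self):
        res = pearson_correlation([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.r == pytest.approx(0.6, abs=1e-12)

    def test_perfect_linear_relations(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert pearson_correlation(x, x).r == pytest.approx(1.0)
        assert pearson_correlation(x, -2 * x + 5).r == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_product_moment_formula(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=40)
        y = 0.3 * x + rng.normal(size=40)
        res = pearson_correlation(x, y)
        assert res.r == pytest.approx(_product_moment(x, y), abs=1e-12)
        assert res.pvalue < 1.0 and abs(res.r) <= 1.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="at least 3"):
            pearson_correlation([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="equal-length"):
            pearson_correlation([1.0, 2.0, 3.0], [1.0, 2.0])


@pytest.fixture(scope="module")
def clean_design():
    rng = np.random.default_rng(21)
    n = 400
    X = pd.DataFrame({
        "const": 1.0,
        "a": rng.normal(size=n),
        "b": rng.uniform(-1, 2, size=n),
    })
    beta = np.array([1.5, -0.8, 2.0])
    y = X.to_numpy() @ beta + rng.normal(0, 0.5, size=n)
    return X, y, beta


class TestRobustLinearModel:
    def test_ols_mode_matches_normal_equations(self, clean_design):
        X, y, _ = clean_design
        fit = RobustLinearModel(y, X).fit(method="ols")
        A = X.to_numpy()
        beta_ne = np.linalg.solve(A.T @ A, A.T @ y)
        np.testing.assert_allclose(fit.params.to_numpy(), beta_ne,
                                   atol=1e-10)

    def test_ols_adjusted_r2_matches_classical_formula(self, clean_design):
        X, y, _ = clean_design
        fit = RobustLinearModel(y, X).fit(method="ols")
        n, p = len(y), 2  # non-constant regressors
        expected = 1 - (1 - fit.rsquared) * (n - 1) / (n - p - 1)
        assert fit.rsquared_adj == pytest.approx(expected, abs=1e-12)
        assert fit.rsquared_adj <= 1.0

    def test_noise_free_data_recovered_exactly(self):
        rng = np.random.default_rng(3)
        n = 200
        X = pd.DataFrame({
            "const": 1.0,
            "sex": rng.integers(0, 2, n).astype(float),
            "age": rng.integers(40, 85, n).astype(float),
            "gps": rng.uniform(15, 40, n),
            "efficiency": rng.uniform(0.2, 1.0, n),
        })
        beta = np.array([28.84, 0.25, 0.05, 0.03, -19.47])
        y = X.to_numpy() @ beta
        fit = RobustLinearModel(y, X).fit(method="mm", seed=0)
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-6)
        assert fit.scale == 0.0 and fit.rsquared == 1.0

    def test_mm_close_to_ols_on_clean_gaussian_data(self, clean_design):
        X, y, _ = clean_design
        mm = RobustLinearModel(y, X).fit(method="mm", seed=1)
        ols = RobustLinearModel(y, X).fit(method="ols")
        np.testing.assert_allclose(mm.params, ols.params, atol=0.05)
        assert (mm.bse > 0).all()
        assert ((mm.pvalues >= 0) & (mm.pvalues <= 1)).all()

    def test_gross_outliers_barely_move_robust_fit(self, clean_design):
        X, y, beta = clean_design
        rng = np.random.default_rng(9)
        y_dirty = y.copy()
        bad = rng.choice(len(y), size=len(y) // 20, replace=False)
        y_dirty[bad] += rng.choice([-10.0, 10.0], size=len(bad))

        ols_clean = RobustLinearModel(y, X).fit(method="ols").params
        ols_dirty = RobustLinearModel(y_dirty, X).fit(method="ols").params
        mm_clean = RobustLinearModel(y, X).fit(method="mm", seed=2).params
        mm_dirty = RobustLinearModel(y_dirty, X).fit(method="mm", seed=2).params

        shift_ols = np.abs(ols_dirty - ols_clean)
        shift_mm = np.abs(mm_dirty - mm_clean)
        # slopes under MM move by < 20% of the OLS displacement
        for name in ("a", "b"):
            assert shift_mm[name] < 0.2 * max(shift_ols[name], 1e-6) \
                or shift_mm[name] < 0.01

    def test_rank_deficiency_names_collinear_column(self, clean_design):
        X, y, _ = clean_design
        X = X.copy()
        X["dup"] = 2.0 * X["a"]
        with pytest.raises(RankDeficientError, match="dup"):
            RobustLinearModel(y, X)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="too few"):
            RobustLinearModel([1.0, 2.0], np.ones((2, 2)))

    def test_summary_mentions_estimator_and_n(self, clean_design):
        X, y, _ = clean_design
        text = RobustLinearModel(y, X).fit(method="mm", seed=0).summary()
        assert "MM robust" in text and "n = 400" in text


class TestModelSpecs:
    def test_covariate_sets_exact(self):
        specs = _specs("baseline_bmi")
        assert specs["M1"].covariates == ("sex", "age", "expenditure",
                                          "intake")
        assert specs["M2"].covariates == ("sex", "age", "efficiency")
        assert specs["M3"].covariates == ("sex", "age", "gps")
        assert specs["M4"].covariates == ("sex", "age", "expenditure",
                                          "intake", "gps")
        assert specs["M5"].covariates == ("sex", "age", "gps", "efficiency")

    def test_sex_and_age_always_required(self):
        with pytest.raises(ValueError, match="sex and age"):
            d.ModelSpec("MX", "baseline_bmi", ("gps",))


class TestModelComparison:
    def test_five_fits_and_efficiency_models_dominate_gps(self, scored_cohort):
        cohort, _ = scored_cohort
        fits = d.model_comparison(cohort, "baseline_bmi", seed=0)
        assert set(fits) == {"M1", "M2", "M3", "M4", "M5"}
        r2 = {k: f.rsquared_adj for k, f in fits.items()}
        assert r2["M2"] > r2["M3"]
        assert r2["M5"] > r2["M3"]
        table = comparison_table(fits)
        assert {"model", "covariate", "coef", "se", "p"} <= set(table.columns)

    def test_women_coded_one(self, scored_cohort):
        cohort, _ = scored_cohort
        shifted = cohort.copy()
        shifted.loc[shifted["sex"] == "F", "bmi_baseline"] += 5.0
        fit = d.fit_model(_specs("baseline_bmi")["M3"], shifted,
                          method="ols")
        base = d.fit_model(_specs("baseline_bmi")["M3"], cohort,
                           method="ols")
        assert fit.params["sex"] - base.params["sex"] == pytest.approx(
            5.0, abs=0.2)

    def test_duplicated_rows_leave_coefficients_unchanged(self, scored_cohort):
        cohort, _ = scored_cohort
        doubled = pd.concat([cohort, cohort], ignore_index=True)
        one = d.fit_model(_specs("baseline_bmi")["M5"], cohort, method="ols")
        two = d.fit_model(_specs("baseline_bmi")["M5"], doubled, method="ols")
        np.testing.assert_allclose(one.params, two.params, atol=1e-10)

    def test_nesting_never_decreases_unadjusted_r2(self, scored_cohort):
        cohort, _ = scored_cohort
        m3 = d.fit_model(_specs("baseline_bmi")["M3"], cohort, method="ols")
        m5 = d.fit_model(_specs("baseline_bmi")["M5"], cohort, method="ols")
        assert m5.results.rsquared >= m3.results.rsquared - 1e-12

    def test_pure_noise_change_outcome_has_tiny_r2(self, scored_cohort):
        cohort, _ = scored_cohort
        fits = d.model_comparison(cohort, "yearly_bmi_change", seed=0)
        for fit in fits.values():
            assert fit.rsquared_adj < 0.04
            assert fit.nobs < len(cohort)  # change filter applied

    def test_listwise_deletion_drops_incomplete_rows(self, scored_cohort):
        cohort, _ = scored_cohort
        holed = cohort.copy()
        holed.loc[holed.index[:25], "gps"] = np.nan
        fit = d.fit_model(_specs("baseline_bmi")["M3"], holed, method="ols")
        assert fit.nobs == len(cohort) - 25


class TestAgeSubgroups:
    def test_strata_partition_cohort(self, scored_cohort):
        cohort, _ = scored_cohort
        fits = d.age_subgroup_fits(cohort, cutoff=60, method="ols")
        assert fits["age<60"].nobs + fits["age>=60"].nobs == len(cohort)

    def test_cutoff_below_min_age_errors(self, scored_cohort):
        cohort, _ = scored_cohort
        with pytest.raises(ValueError, match="empty age stratum"):
            d.age_subgroup_fits(cohort, cutoff=10, method="ols")

    def test_homogeneous_effect_agrees_across_strata(self, scored_cohort):
        cohort, _ = scored_cohort
        fits = d.age_subgroup_fits(cohort, cutoff=60, method="ols")
        lo, hi = fits["age<60"], fits["age>=60"]
        for name in ("gps", "efficiency"):
            joint_se = np.hypot(lo.bse[name], hi.bse[name])
            assert abs(lo.params[name] - hi.params[name]) < 4 * joint_se


class TestQuartileSummary:
    def test_group_sizes_differ_by_at_most_one(self, scored_cohort):
        cohort, _ = scored_cohort
        tab = d.quartile_summary(cohort)
        assert len(tab) == 4
        assert tab["n"].max() - tab["n"].min() <= 1
        assert tab["n"].sum() == len(cohort)
        assert tab["mean_efficiency"].is_monotonic_increasing

    def test_efficient_quartile_exercises_less_eats_more(self, scored_cohort):
        # expenditure is a DEA input: the efficient frontier sits at low
        # expenditure and high intake for a given BMI
        cohort, _ = scored_cohort
        tab = d.quartile_summary(cohort).set_index("quartile")
        assert tab.loc["Q4", "mean_expenditure_mets_h"] < tab.loc[
            "Q1", "mean_expenditure_mets_h"]
        assert tab.loc["Q4", "mean_inverse_intake"] < tab.loc[
            "Q1", "mean_inverse_intake"]

    def test_identical_subjects_tie_handling(self):
        cohort = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(8)],
            "efficiency": 0.5,
            "energy_expenditure_mets_h": 30.0,
            "energy_intake_kcal": 2000.0,
        })
        tab = d.quartile_summary(cohort)
        assert tab["mean_expenditure_mets_h"].nunique() == 1
        assert tab["n"].tolist() == [2, 2, 2, 2]

    def test_too_small_cohort_rejected(self):
        cohort = pd.DataFrame({
            "subject_id": ["a", "b", "c"], "efficiency": [0.5, 0.6, 0.7],
            "energy_expenditure_mets_h": 30.0,
            "energy_intake_kcal": 2000.0})
        with pytest.raises(ValueError, match="at least 4"):
            d.quartile_summary(cohort)


class TestParameterRecoverySingleCohort:
    def test_m4_recovers_truth_within_two_se(self):
        cfg = d.SimConfig(n_subjects=2000, seed=271)
        cohort, *_, truth = d.simulate_cohort(cfg)
        fit = d.fit_model(_specs("baseline_bmi")["M4"], cohort, seed=0)
        targets = {"const": truth["b0"], "sex": truth["b_sex"],
                   "age": truth["b_age"],
                   "expenditure": truth["delta_expenditure"],
                   "intake": truth["delta_intake"],
                   "gps": truth["gamma_gps"]}
        misses = [k for k, v in targets.items()
                  if abs(fit.params[k] - v) > 2 * fit.bse[k]]
        # ~95% joint behaviour: allow at most one marginal excursion
        assert len(misses) <= 1, misses
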