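"""AUC biomarkers, stepwise-AIC selection, Type II ANOVA, partial residuals."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.formula.api import ols

from hepaflux.errors import DesignError, UndefinedValueError
from hepaflux.outcome_model import (
    BiomarkerSeries,
    assemble_design,
    build_cohort_table,
    cohort_aucs,
    fit_and_anova,
    partial_residuals,
    stepwise_aic,
    time_auc,
    type2_ss,
)

from conftest import exhaustive_hierarchical_aic, random_regression_dataset


def fine_grid_auc(t, v, window, m=20001):
    """Independent AUC oracle: dense trapezoid on the union of a fine grid
    and the observation knots, clipped without extrapolation."""
    lo = max(window[0], t[0])
    hi = min(window[1], t[-1])
    grid = np.union1d(np.linspace(lo, hi, m), t[(t >= lo) & (t <= hi)])
    return np.trapezoid(np.interp(grid, t, v), grid)


class TestTimeAuc:
    def test_rectangle(self):
        t = np.array([0.0, 1.0, 6.0])
        assert time_auc(t, np.full(3, 0.8), (0.0, 6.0)) == pytest.approx(4.8)

    def test_triangle(self):
        t = np.array([0.0, 6.0])
        assert time_auc(t, np.array([0.0, 6.0]), (0.0, 6.0)) == pytest.approx(18.0)

    def test_irregular_grid_matches_fine_grid_oracle(self):
        rng = np.random.default_rng(42)
        t = np.sort(rng.uniform(-1.0, 9.0, 9))
        v = rng.normal(size=9)
        for window in [(0.0, 6.0), (-2.0, 4.0), (1.5, 20.0)]:
            mine = time_auc(t, v, window)
            assert mine == pytest.approx(fine_grid_auc(t, v, window), abs=1e-9)

    def test_no_extrapolation_beyond_observations(self):
        t = np.array([2.0, 4.0])
        v = np.array([1.0, 1.0])
        # window [0, 6] but observations span [2, 4]: integral over 2 h only
        assert time_auc(t, v, (0.0, 6.0)) == pytest.approx(2.0)

    def test_fewer_than_two_observations_gives_nan(self):
        t = np.array([0.0, 5.0, 10.0])
        v = np.array([1.0, 1.0, 1.0])
        assert np.isnan(time_auc(t, v, (4.0, 6.0)))

    def test_linearity_on_fixed_grid(self):
        t = np.array([0.0, 1.0, 3.0, 6.0])
        v = np.array([0.2, 0.5, 0.1, 0.9])
        a, c, window = 2.5, -1.0, (0.0, 6.0)
        lhs = time_auc(t, a * v + c, window)
        rhs = a * time_auc(t, v, window) + c * (window[1] - window[0])
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_time_average_variant(self):
        t = np.array([0.0, 6.0])
        v = np.array([0.8, 0.8])
        assert time_auc(t, v, (0.0, 6.0), time_average=True) == pytest.approx(0.8)

    def test_biomarker_series_validation(self):
        with pytest.raises(UndefinedValueError):
            BiomarkerSeries("L1", "pl_eff", np.array([1.0, 1.0]), np.array([0.1, 0.2]))


class TestAssembleDesign:
    def _cohort(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "a": rng.normal(size=n),
                "b": rng.normal(size=n),
                "y": rng.normal(size=n),
            }
        )

    def test_interaction_column_is_elementwise_product(self):
        cohort = self._cohort()
        table = assemble_design(cohort, ["a", "b"], [("a", "b")], outcome="y")
        assert list(table.columns) == ["a", "b", "y", "a:b"]
        np.testing.assert_allclose(table["a:b"], table["a"] * table["b"])

    def test_residual_df_matches_four_term_model_on_twenty_cases(self):
        cohort = self._cohort(n=20)
        table = assemble_design(cohort, ["a", "b"], [("a", "b")], outcome="y")
        table["c"] = np.arange(20.0)
        fit = fit_and_anova(table, ["a", "b", "c", "a:b"], "y")
        assert fit.f_df == (4, 15)

    def test_zero_variance_predictor_named(self):
        cohort = self._cohort()
        cohort["flat"] = 1.0
        with pytest.raises(DesignError, match="flat"):
            assemble_design(cohort, ["a", "flat"], outcome="y")

    def test_incomplete_rows_dropped(self):
        cohort = self._cohort()
        cohort.loc[3, "a"] = np.nan
        table = assemble_design(cohort, ["a", "b"], outcome="y")
        assert len(table) == 19


class TestStepwiseAic:
    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(2024)
        for _ in range(10):
            table, scope = random_regression_dataset(rng)
            greedy = stepwise_aic(table, "y", scope)
            exhaustive = exhaustive_hierarchical_aic(table, "y", scope)
            assert greedy == exhaustive

    def test_noiseless_planted_model_recovered_exactly(self):
        rng = np.random.default_rng(7)
        n = 60
        x = rng.standard_normal((n, 4))
        table = pd.DataFrame({f"x{i}": x[:, i] for i in range(4)})
        table["y"] = 2.0 * table["x0"] - 1.5 * table["x2"]
        selected = stepwise_aic(table, "y", ["x0", "x1", "x2", "x3"])
        assert selected == ["x0", "x2"]

    def test_hierarchy_blocks_orphan_interaction(self):
        rng = np.random.default_rng(11)
        n = 200
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        table = pd.DataFrame({"a": a, "b": b, "a:b": a * b})
        # signal purely in the product: hierarchy forces parents in first,
        # so the selected set must contain both parents if it has the product
        table["y"] = 3.0 * a * b + 0.1 * rng.standard_normal(n)
        selected = stepwise_aic(table, "y", ["a", "b", "a:b"])
        if "a:b" in selected:
            assert {"a", "b"} <= set(selected)

    def test_underdetermined_scope_rejected(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 1.0, 4.0],
                              "c": [0.5, 0.1, 0.9], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(DesignError):
            stepwise_aic(table, "y", ["a", "b", "c"])


class TestTypeIIAnova:
    def _random_design(self, rng, n=40):
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        table = pd.DataFrame({"a": a, "b": b, "a:b": a * b})
        table["y"] = 1.0 + a - 0.5 * b + 0.8 * a * b + rng.standard_normal(n)
        return table

    def test_matches_statsmodels_type2(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            table = self._random_design(rng)
            fit = fit_and_anova(table, ["a", "b", "a:b"], "y")
            sm_fit = ols("y ~ a + b + a:b", data=table).fit()
            sm_anova = sm.stats.anova_lm(sm_fit, typ=2)
            for term, sm_term in [("a", "a"), ("b", "b"), ("a:b", "a:b")]:
                row = fit.terms[fit.terms["term"] == term].iloc[0]
                assert row["ss2"] == pytest.approx(sm_anova.loc[sm_term, "sum_sq"], rel=1e-8)
                assert row["p"] == pytest.approx(sm_anova.loc[sm_term, "PR(>F)"], rel=1e-6)

    def test_orthogonal_design_type2_equals_type1(self):
        # balanced +/-1 factors are exactly orthogonal
        a = np.array([-1.0, -1.0, 1.0, 1.0] * 5)
        b = np.array([-1.0, 1.0] * 10)
        rng = np.random.default_rng(5)
        table = pd.DataFrame({"a": a, "b": b})
        table["y"] = a + 0.5 * b + rng.standard_normal(20)
        fit = fit_and_anova(table, ["a", "b"], "y")
        sm_fit = ols("y ~ a + b", data=table).fit()
        type1 = sm.stats.anova_lm(sm_fit, typ=1)
        for term in ("a", "b"):
            row = fit.terms[fit.terms["term"] == term].iloc[0]
            assert row["ss2"] == pytest.approx(type1.loc[term, "sum_sq"], rel=1e-9)

    def test_overall_f_matches_r2_closed_form(self):
        rng = np.random.default_rng(9)
        table = self._random_design(rng, n=20)
        fit = fit_and_anova(table, ["a", "b", "a:b"], "y")
        k, df_resid = fit.f_df
        closed = (fit.r2 / k) / ((1.0 - fit.r2) / df_resid)
        assert fit.f_statistic == pytest.approx(closed, rel=1e-9)
        assert fit.adj_r2 <= fit.r2

    def test_standardized_beta_definition(self):
        rng = np.random.default_rng(13)
        table = self._random_design(rng)
        fit = fit_and_anova(table, ["a", "b"], "y")
        row = fit.terms[fit.terms["term"] == "a"].iloc[0]
        expected = row["b"] * table["a"].std(ddof=1) / table["y"].std(ddof=1)
        assert row["beta"] == pytest.approx(expected, rel=1e-12)

    def test_singular_design_rejected(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(30)
        table = pd.DataFrame({"a": a, "b": 2.0 * a, "y": rng.standard_normal(30)})
        with pytest.raises(DesignError):
            fit_and_anova(table, ["a", "b"], "y")


class TestPartialResiduals:
    def test_slope_identity_and_direct_definition(self):
        rng = np.random.default_rng(21)
        n = 50
        table = pd.DataFrame(
            {"a": rng.standard_normal(n), "b": rng.standard_normal(n)}
        )
        table["y"] = 2.0 + table["a"] - 0.7 * table["b"] + rng.standard_normal(n)
        fit = fit_and_anova(table, ["a", "b"], "y")
        pr = partial_residuals(fit, "a")

        # direct definition from an independent OLS fit
        X = sm.add_constant(table[["a", "b"]])
        res = sm.OLS(table["y"], X).fit()
        direct = res.resid.to_numpy() + res.params["a"] * table["a"].to_numpy()
        np.testing.assert_allclose(pr, direct, atol=1e-9)

        # regressing partial residuals on x_a recovers exactly b_a
        x = table["a"].to_numpy()
        slope = np.polyfit(x, pr, 1)[0]
        assert slope == pytest.approx(fit.coefficient("a"), abs=1e-9)

    def test_unknown_term_rejected(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "y": [1.0, 2.0, 2.5, 4.0]})
        fit = fit_and_anova(table, ["a"], "y")
        with pytest.raises(DesignError):
            partial_residuals(fit, "nope")


def test_cohort_aucs_and_join():
    biomarkers = pd.DataFrame(
        {
            "liver_id": ["A"] * 3 + ["B"] * 3,
            "time_h": [0.0, 1.0, 6.0] * 2,
            "parameter": ["pl_eff"] * 6,
            "value": [0.8, 0.8, 0.8, 0.5, 0.6, 0.7],
        }
    )
    outcomes = pd.DataFrame({"liver_id": ["A", "B"], "lgraft": [-1.0, 2.0]})
    cohort = build_cohort_table(biomarkers, outcomes, ["pl_eff"])
    assert cohort.loc[cohort["liver_id"] == "A", "pl_eff_auc"].iloc[0] == pytest.approx(4.8)
    trapz_b = 0.5 * (0.5 + 0.6) * 1.0 + 0.5 * (0.6 + 0.7) * 5.0
    assert cohort.loc[cohort["liver_id"] == "B", "pl_eff_auc"].iloc[0] == pytest.approx(trapz_b)
    assert list(cohort.columns) == ["liver_id", "pl_eff_auc", "lgraft"]
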