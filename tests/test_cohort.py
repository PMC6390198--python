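"""Nested mixed models, covariance selection and ddCt genotyping."""

import numpy as np
import pandas as pd
import pytest

from entophys.cohort import (
    ModelSpec,
    ddct_genotype,
    fit_lmm,
    fraction_percent,
    select_covariance,
)
from entophys.synth.cohorts import CohortSpec, generate_cohort


def _basic_spec(response="sag_ratio"):
    return ModelSpec(response=response,
                     fixed=["genotype", "age", "sex", "setup"])


class TestFitLMM:
    def test_zero_animal_variance_matches_ols(self):
        """With no between-animal variance the balanced mixed model
        reproduces ordinary least squares on the same design."""
        import statsmodels.api as sm

        table, _ = generate_cohort(CohortSpec(
            n_animals_per_genotype=10, cells_per_animal=4,
            genotype_effect=0.05, animal_sd=0.0, residual_sd=0.05,
            seed=11))
        fit = fit_lmm(table, _basic_spec())

        dummies = pd.get_dummies(
            table[["genotype", "age", "sex", "setup"]], drop_first=True,
            dtype=float)
        X = sm.add_constant(dummies.to_numpy())
        ols = sm.OLS(table["sag_ratio"].to_numpy(), X).fit()
        # dummy coding puts "+/+" first, so the fitted coefficient is the
        # -/- offset; compare it directly with the OLS column
        got = fit.coef("genotype[-/-]")
        want = ols.params[1]
        assert got == pytest.approx(want, abs=1e-6)
        contrast = fit.contrast("genotype", level_hi="+/+",
                                level_lo="-/-")
        assert contrast["estimate"] == pytest.approx(-want, abs=1e-6)

    def test_agrees_with_statsmodels_mixedlm(self):
        """Independent route: statsmodels MixedLM on the same data gives
        the same genotype coefficient and similar variance components."""
        import statsmodels.formula.api as smf

        table, _ = generate_cohort(CohortSpec(
            n_animals_per_genotype=12, cells_per_animal=4,
            genotype_effect=0.04, animal_sd=0.03, residual_sd=0.05,
            seed=5))
        fit = fit_lmm(table, _basic_spec())
        ml = smf.mixedlm(
            "sag_ratio ~ C(genotype) + C(age) + C(sex) + C(setup)",
            table, groups=table["animal_id"],
        ).fit(reml=True)
        assert fit.coef("genotype[-/-]") == pytest.approx(
            ml.params["C(genotype)[T.-/-]"], abs=1e-3)
        assert fit.variance_components["animal_sd"] ** 2 == pytest.approx(
            float(ml.cov_re.iloc[0, 0]), abs=2e-4)

    def test_marginal_means_shift_with_the_response(self):
        table, _ = generate_cohort(CohortSpec(
            n_animals_per_genotype=8, cells_per_animal=3,
            genotype_effect=0.02, seed=3))
        fit1 = fit_lmm(table, _basic_spec())
        shifted = table.copy()
        shifted["sag_ratio"] = shifted["sag_ratio"] + 1.0
        fit2 = fit_lmm(shifted, _basic_spec())
        em1 = fit1.emmeans["emmean"].to_numpy()
        em2 = fit2.emmeans["emmean"].to_numpy()
        assert np.allclose(em2 - em1, 1.0, atol=1e-4)

    def test_interactions_can_be_declared(self):
        table, _ = generate_cohort(CohortSpec(
            n_animals_per_genotype=8, cells_per_animal=3, seed=9))
        spec = ModelSpec(response="sag_ratio",
                         fixed=["genotype", "age", "sex", "setup"],
                         interactions=[("genotype", "age")])
        fit = fit_lmm(table, spec)
        assert "genotype:age" in fit.tests


class TestCovarianceSelection:
    def _repeated_spec(self, covariance="compound_symmetry"):
        return ModelSpec(response="sag_ratio",
                         fixed=["genotype", "sex", "ap_number"],
                         random_group="animal_id", subject="cell_id",
                         within="ap_number", covariance=covariance)

    def test_compound_symmetry_data_selects_compound_symmetry(self):
        wins = 0
        n = 30
        for seed in range(n):
            table, _ = generate_cohort(CohortSpec(
                n_animals_per_genotype=6, cells_per_animal=3,
                within_levels=4, within_structure="compound_symmetry",
                cell_sd=0.06, residual_sd=0.04, animal_sd=0.02,
                seed=seed))
            sel = select_covariance(table, self._repeated_spec())
            wins += sel.chosen == "compound_symmetry"
        assert wins > n / 2

    def test_heteroscedastic_data_selects_diagonal(self):
        wins = 0
        n = 30
        for seed in range(n):
            table, _ = generate_cohort(CohortSpec(
                n_animals_per_genotype=6, cells_per_animal=3,
                within_levels=4, within_structure="diagonal",
                level_sds=(0.01, 0.03, 0.09, 0.27), animal_sd=0.02,
                seed=100 + seed))
            sel = select_covariance(table, self._repeated_spec())
            wins += sel.chosen == "diagonal"
        assert wins > n / 2

    def test_criteria_table_lists_all_candidates(self):
        table, _ = generate_cohort(CohortSpec(
            n_animals_per_genotype=6, cells_per_animal=3,
            within_levels=3, cell_sd=0.05, seed=1))
        sel = select_covariance(table, self._repeated_spec())
        assert set(sel.criteria.structure) == {"compound_symmetry",
                                               "diagonal"}
        assert np.isfinite(sel.fit.aic)


class TestDdct:
    def test_reference_sample_is_homozygous_unity(self):
        res = ddct_genotype(20.0, 18.0, 20.0, 18.0)
        assert res.ddct == pytest.approx(0.0)
        assert res.relative_quantity == pytest.approx(1.0)
        assert res.call == "homozygous"

    def test_one_cycle_later_is_hemizygous(self):
        res = ddct_genotype(21.0, 18.0, 20.0, 18.0)
        assert res.relative_quantity == pytest.approx(0.5)
        assert res.call == "hemizygous"

    def test_undetermined_target_is_negative(self):
        res = ddct_genotype(None, 18.0, 20.0, 18.0)
        assert res.call == "negative"
        res = ddct_genotype(float("nan"), 18.0, 20.0, 18.0)
        assert res.call == "negative"

    def test_relative_quantity_halves_per_cycle(self):
        prev = None
        for extra in range(4):
            res = ddct_genotype(20.0 + extra, 18.0, 20.0, 18.0)
            if prev is not None:
                assert res.relative_quantity == pytest.approx(prev / 2.0)
            prev = res.relative_quantity


class TestProportions:
    @pytest.mark.parametrize("count,total,expected", [
        (31, 35, 89.0),    # iAb-positive fan cells
        (25, 26, 96.0),    # iAb-positive stellate cells
        (101, 127, 80.0),  # fan-cell morphology fraction
        (73, 80, 91.0),    # stellate-cell morphology fraction
    ])
    def test_reported_percentages(self, count, total, expected):
        assert fraction_percent(count, total) == expected
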