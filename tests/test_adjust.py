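"""Correction model: fitting, truncated differences, application of the
log-scale correction, orchestration and prevalence."""

import numpy as np
import pandas as pd
import pytest

from inflammadjust import adjust
from inflammadjust.adjust import (
    adjust_biomarker,
    apply_adjustment,
    compare_with_covariate,
    fit_model,
    prevalence,
    reference_difference,
)
from inflammadjust.registry import ReferenceValues, external_reference
from inflammadjust.synthetic import BiomarkerParams, default_config, generate_survey


def make_model(biomarker="ferritin", markers=("AGP", "CRP"), beta1=None, beta2=None,
               intercept=0.0):
    return adjust.AdjustmentModel(
        biomarker=biomarker,
        markers_in_model=tuple(markers),
        intercept=intercept,
        beta1=beta1,
        beta2=beta2,
        n_used=100,
    )


PSC_REFS = ReferenceValues(group="PSC", agp_ref=0.59, crp_ref=0.10)


class TestReferenceDifference:
    def test_inflamed_child_worked_example(self):
        assert round(reference_difference(np.log(2.1), np.log(0.59)), 2) == 1.27

    def test_below_reference_truncates_to_zero(self):
        assert reference_difference(np.log(0.3), np.log(0.59)) == 0.0

    def test_equality_yields_zero(self):
        assert reference_difference(np.log(0.59), np.log(0.59)) == 0.0

    def test_missing_propagates(self):
        out = reference_difference(pd.Series([np.nan, np.log(2.0)]), np.log(0.59))
        assert np.isnan(out[0]) and out[1] > 0

    def test_vectorized(self):
        out = reference_difference(np.log([0.3, 0.59, 2.1]), np.log(0.59))
        assert out[0] == out[1] == 0.0 and out[2] > 0

    def test_nonfinite_reference_rejected(self):
        with pytest.raises(ValueError):
            reference_difference(0.5, np.inf)


class TestFitModel:
    def test_recovers_generating_slopes_within_three_se(self):
        config = default_config("PSC", n=2000, seed=11, biomarkers={
            "retinol": BiomarkerParams(intercept=0.0, beta_agp=-0.3, beta_crp=-0.1,
                                       noise_sd=0.3)})
        t = generate_survey(config)
        m = fit_model(np.log(t["retinol"]), np.log(t["agp"]), np.log(t["crp"]))
        assert abs(m.beta1 - (-0.3)) < 3 * m.stderr["ln_agp"]
        assert abs(m.beta2 - (-0.1)) < 3 * m.stderr["ln_crp"]
        assert m.n_used == 2000

    def test_null_slopes_estimated_near_zero(self):
        config = default_config("PSC", n=5000, seed=12, biomarkers={
            "zinc": BiomarkerParams(intercept=4.0, beta_agp=0.0, beta_crp=0.0,
                                    noise_sd=0.2)})
        t = generate_survey(config)
        m = fit_model(np.log(t["zinc"]), np.log(t["agp"]), np.log(t["crp"]))
        assert abs(m.beta1) < 3 * m.stderr["ln_agp"]
        assert abs(m.beta2) < 3 * m.stderr["ln_crp"]

    def test_single_marker_model(self, psc_table):
        m = fit_model(np.log(psc_table["stfr"]), ln_agp=np.log(psc_table["agp"]))
        assert m.markers_in_model == ("AGP",)
        assert m.beta1 is not None and m.beta2 is None

    def test_covariate_enters_fit(self, rng):
        n = 500
        ln_agp = rng.normal(0, 0.5, n)
        mal = rng.binomial(1, 0.4, n)
        ln_mb = 1.0 + 0.5 * ln_agp + 0.8 * mal + rng.normal(0, 0.2, n)
        m = fit_model(pd.Series(ln_mb), pd.Series(ln_agp),
                      covariates=pd.DataFrame({"malaria": mal}))
        assert m.covariate_coefficients["malaria"] == pytest.approx(0.8, abs=0.1)

    def test_rank_deficiency_raises(self):
        n = 100
        with pytest.raises(ValueError, match="rank"):
            fit_model(pd.Series(np.random.default_rng(0).normal(size=n)),
                      pd.Series(np.zeros(n)))

    def test_too_few_complete_cases_raise(self):
        with pytest.raises(ValueError, match="complete"):
            fit_model(pd.Series([1.0] * 10), pd.Series(np.arange(10.0)))

    def test_requires_at_least_one_marker(self):
        with pytest.raises(ValueError):
            fit_model(pd.Series([1.0, 2.0]))


class TestApplyAdjustment:
    def test_zero_coefficients_are_identity(self, psc_table):
        model = make_model(beta1=0.0, beta2=0.0)
        res = apply_adjustment(psc_table, model, PSC_REFS, biomarker_col="ferritin")
        pd.testing.assert_series_equal(res.frame["mb_adj"], res.frame["mb_unadj"],
                                       check_names=False)

    def test_matches_hand_computed_oracle(self):
        """Five rows evaluated spreadsheet-style (row-by-row scalar
        arithmetic, frozen) against the vectorised implementation."""
        table = pd.DataFrame({
            "ferritin": [50.0, 12.0, 30.0, 80.0, 5.0],
            "agp": [2.1, 0.3, 0.59, 1.0, 0.45],
            "crp": [5.0, 0.05, 0.10, 0.08, 2.0],
        })
        model = make_model(beta1=0.8, beta2=0.3)
        res = apply_adjustment(table, model, PSC_REFS)
        expected = [5.599963245132135, 12.0, 30.0,
                    52.453152663136066, 2.0354526576845218]
        np.testing.assert_allclose(res.frame["mb_adj"], expected, rtol=1e-10)

    def test_rows_below_reference_unchanged_exactly(self):
        table = pd.DataFrame({"ferritin": [10.0, 20.0],
                              "agp": [0.5, 0.59], "crp": [0.05, 0.10]})
        model = make_model(beta1=0.8, beta2=0.3)
        res = apply_adjustment(table, model, PSC_REFS)
        assert (res.frame["mb_adj"] == res.frame["mb_unadj"]).all()

    def test_missing_marker_gives_missing_adjusted_value(self):
        table = pd.DataFrame({"ferritin": [10.0, 20.0],
                              "agp": [2.0, np.nan], "crp": [1.0, 1.0]})
        model = make_model(beta1=0.8, beta2=0.3)
        res = apply_adjustment(table, model, PSC_REFS)
        assert res.frame["adjusted_flag"].tolist() == [True, False]
        assert np.isnan(res.frame.loc[1, "mb_adj"])

    def test_marker_without_reference_rejected(self):
        table = pd.DataFrame({"ferritin": [10.0], "agp": [2.0], "crp": [1.0]})
        model = make_model(beta1=0.8, beta2=0.3)
        refs = ReferenceValues(group="MANUAL", agp_ref=0.59, crp_ref=None,
                               agp_source="user", crp_source="user")
        with pytest.raises(ValueError, match="CRP"):
            apply_adjustment(table, model, refs)

    def test_nonpositive_values_are_hard_errors(self):
        table = pd.DataFrame({"ferritin": [10.0, 0.0], "agp": [1.0, 1.0],
                              "crp": [0.5, 0.5]})
        model = make_model(beta1=0.8, beta2=0.3)
        with pytest.raises(ValueError, match="nonpositive"):
            apply_adjustment(table, model, PSC_REFS)


class TestDirectionProperties:
    def test_positive_betas_never_increase(self, psc_table):
        res = adjust_biomarker(psc_table, "ferritin", "PSC")
        f = res.frame
        assert (f["mb_adj"] <= f["mb_unadj"]).all()
        no_excess = (f["ln_agp_diff"] == 0) & (f["ln_crp_diff"] == 0)
        assert (f.loc[no_excess, "mb_adj"] == f.loc[no_excess, "mb_unadj"]).all()
        assert (f.loc[~no_excess, "mb_adj"] < f.loc[~no_excess, "mb_unadj"]).all()

    def test_negative_betas_never_decrease(self, psc_table):
        res = adjust_biomarker(psc_table, "retinol", "PSC")
        f = res.frame
        assert (f["mb_adj"] >= f["mb_unadj"]).all()

    def test_idempotent_on_uninflamed_population(self, psc_table):
        """When nobody exceeds the reference deciles there is nothing to
        correct and the data come back unchanged."""
        calm = psc_table.copy()
        calm["agp"] = np.minimum(calm["agp"], 0.59)
        calm["crp"] = np.minimum(calm["crp"], 0.10)
        res = adjust_biomarker(calm, "ferritin", "PSC")
        assert (res.frame["mb_adj"] == res.frame["mb_unadj"]).all()


class TestAdjustBiomarker:
    def test_never_adjusted_biomarker_passes_through(self, wra_table):
        t = wra_table.copy()
        t["b12"] = 300.0 + np.arange(len(t), dtype=float)
        res = adjust_biomarker(t, "b12", "WRA")
        assert not res.adjusted
        assert (res.frame["mb_adj"] == t["b12"]).all()
        assert not res.frame["adjusted_flag"].any()

    def test_stfr_uses_agp_only(self, psc_table):
        res = adjust_biomarker(psc_table, "stfr", "PSC")
        assert res.model.markers_in_model == ("AGP",)
        assert res.model.beta2 is None
        assert res.frame["ln_crp_diff"].isna().all()

    def test_zinc_without_correlation_left_alone(self):
        config = default_config("PSC", n=1500, seed=21, biomarkers={
            "zinc": BiomarkerParams(intercept=4.25, beta_agp=0.0, beta_crp=0.0,
                                    noise_sd=0.18)})
        t = generate_survey(config)
        res = adjust_biomarker(t, "zinc", "PSC")
        assert not res.adjusted
        assert "Spearman" in res.reason

    def test_zinc_with_confounding_adjusted(self, psc_table):
        res = adjust_biomarker(psc_table, "zinc", "PSC")
        assert res.adjusted
        assert res.model.beta1 < 0

    def test_zinc_in_wra_never_adjusted(self, wra_table):
        res = adjust_biomarker(wra_table, "zinc", "WRA")
        assert not res.adjusted

    def test_missing_inflammation_columns_raise(self, psc_table):
        t = psc_table.drop(columns=["agp", "crp"])
        with pytest.raises(ValueError, match="inflammation"):
            adjust_biomarker(t, "ferritin", "PSC")

    def test_single_available_marker_still_used(self, psc_table):
        t = psc_table.drop(columns=["crp"])
        res = adjust_biomarker(t, "ferritin", "PSC")
        assert res.adjusted and res.model.markers_in_model == ("AGP",)

    def test_refs_override_changes_truncation(self, psc_table):
        high = ReferenceValues(group="MANUAL", agp_ref=5.0, crp_ref=50.0,
                               agp_source="user", crp_source="user")
        res = adjust_biomarker(psc_table, "ferritin", "PSC", refs_override=high)
        # nearly nobody exceeds such extreme references
        assert (res.frame["ln_agp_diff"] == 0).mean() > 0.99


class TestPrevalence:
    def test_simple_count_below(self):
        assert prevalence([1.0, 2.0, 3.0, 4.0], cutoff=2.5) == 50.0

    def test_above_direction(self):
        assert prevalence([5.0, 9.0, 10.0], cutoff=8.3, direction="above") == pytest.approx(200 / 3)

    def test_missing_excluded_from_denominator(self):
        assert prevalence([1.0, np.nan, 3.0], cutoff=2.0) == 50.0

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            prevalence([np.nan, np.nan], cutoff=1.0)

    def test_standard_error_binomial(self):
        pct, se = prevalence([1.0, 2.0, 3.0, 4.0], cutoff=2.5, with_se=True)
        assert pct == 50.0
        assert se == pytest.approx(100 * np.sqrt(0.5 * 0.5 / 4))

    def test_weights(self):
        got = prevalence([1.0, 4.0], cutoff=2.0, weights=[3.0, 1.0])
        assert got == 75.0

    def test_adjustment_shifts_prevalence_with_coefficient_sign(self, psc_table):
        """Positive slopes pull adjusted ferritin down, so deficiency
        prevalence can only rise."""
        res = adjust_biomarker(psc_table, "ferritin", "PSC")
        p_unadj = prevalence(res.frame["mb_unadj"], cutoff=12.0)
        p_adj = prevalence(res.frame["mb_adj"], cutoff=12.0)
        assert p_adj >= p_unadj


class TestCovariateComparison:
    def test_constant_covariate_rejected(self, psc_table):
        t = psc_table.copy()
        t["malaria"] = 0
        with pytest.raises(ValueError, match="constant"):
            compare_with_covariate(t, "ferritin", "PSC", "malaria", cutoff=12.0)

    def test_null_covariate_leaves_prevalence_alone(self):
        config = default_config("PSC", n=2000, seed=31, malaria_prevalence=0.3)
        t = generate_survey(config)
        cmp = compare_with_covariate(t, "ferritin", "PSC", "malaria", cutoff=12.0)
        assert abs(cmp.difference) < 2.0  # percentage points, one replicate
        assert cmp.model_with.covariate_coefficients
        assert not cmp.model_without.covariate_coefficients

    def test_strong_covariate_effect_reported_not_subtracted(self):
        biomarkers = {"ferritin": BiomarkerParams(intercept=np.log(30.0), beta_agp=0.8,
                                                  beta_crp=0.3, noise_sd=0.6,
                                                  malaria_effect=0.7)}
        config = default_config("PSC", n=2000, seed=32, malaria_prevalence=0.3,
                                biomarkers=biomarkers)
        t = generate_survey(config)
        cmp = compare_with_covariate(t, "ferritin", "PSC", "malaria", cutoff=12.0)
        assert cmp.model_with.covariate_coefficients["malaria"] == pytest.approx(0.7, abs=0.15)
        assert np.isfinite(cmp.difference)
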