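"""Mixed-model engine: cross-checks, recovery, optimisation, classification."""

from dataclasses import replace

import numpy as np
import pytest
import statsmodels.formula.api as smf

from phenokit.mixed_model import (
    ALPHA,
    FitError,
    ModelSpec,
    SexEffects,
    classify_effect,
    estimate_effects,
    fit_model,
    genotype_test,
    likelihood_ratio_test,
    mm_analyse,
    optimise_model,
    start_spec,
    test_batch_significance as batch_significance_test,
    test_variance_homogeneity as variance_homogeneity_test,
)
from phenokit.synthetic import SyntheticSpec, synthetic_phenlist


def _sm_frame(pl):
    df = pl.frame.copy()
    df["geno"] = (df["Genotype"] == pl.test_genotype).astype(float)
    df["male"] = (df["Sex"] == "male").astype(float)
    df["gxs"] = df["geno"] * df["male"]
    return df


class TestFitEngine:
    def test_reml_matches_statsmodels_mixedlm(self, mm_phenlist):
        pl, _ = mm_phenlist
        fm = fit_model(pl, ModelSpec(dep_var="response", fit_objective="REML"))
        df = _sm_frame(pl)
        sm_fit = smf.mixedlm("response ~ geno + male + gxs", df, groups=df["Batch"]).fit(
            reml=True, method="lbfgs"
        )
        assert fm.loglik == pytest.approx(sm_fit.llf, abs=1e-4)
        np.testing.assert_allclose(
            fm.coefficients[["Intercept", "Genotype", "Sex", "Genotype:Sex"]].to_numpy(),
            sm_fit.fe_params.to_numpy(), rtol=1e-4,
        )
        assert fm.batch_variance == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]), rel=1e-2)
        assert fm.residual_variances["all"] == pytest.approx(sm_fit.scale, rel=1e-3)

    def test_ml_matches_statsmodels_mixedlm(self):
        spec = SyntheticSpec(batch_sd=8.0, n_test={"male": 30, "female": 30}, seed=21)
        pl, _ = synthetic_phenlist(spec)
        fm = fit_model(pl, ModelSpec(dep_var="response", fit_objective="ML"))
        df = _sm_frame(pl)
        sm_fit = smf.mixedlm("response ~ geno + male + gxs", df, groups=df["Batch"]).fit(
            reml=False, method="lbfgs"
        )
        assert fm.loglik == pytest.approx(sm_fit.llf, abs=1e-3)

    def test_zero_batch_variance_matches_ols(self):
        spec = SyntheticSpec(batch_sd=0.0, seed=5)
        pl, _ = synthetic_phenlist(spec)
        fm = fit_model(pl, ModelSpec(dep_var="response", fit_objective="REML"))
        df = _sm_frame(pl)
        ols = smf.ols("response ~ geno + male + gxs", df).fit()
        assert fm.batch_variance == pytest.approx(0.0, abs=1e-6 * ols.scale)
        np.testing.assert_allclose(
            fm.coefficients.to_numpy(), ols.params.to_numpy(), rtol=1e-6
        )

    def test_parameter_recovery_within_3_se(self):
        spec = SyntheticSpec(
            n_control={"male": 75, "female": 75}, n_test={"male": 75, "female": 75},
            n_batches=15, n_test_batches=15, batch_sd=5.0,
            genotype_effect={"male": -25.0, "female": -15.0}, seed=9,
        )
        pl, truth = synthetic_phenlist(spec)
        fm = fit_model(pl, start_spec("response"))
        eff = estimate_effects(fm)
        assert abs(eff.male[0] - truth.genotype_effect["male"]) < 3 * eff.male[1]
        assert abs(eff.female[0] - truth.genotype_effect["female"]) < 3 * eff.female[1]

    def test_heterogeneous_fit_recovers_variance_ratio(self, het_phenlist):
        pl, truth = het_phenlist
        fm = fit_model(pl, ModelSpec(dep_var="response", residual_variance="per_genotype"))
        ratio = fm.residual_variances["mutant"] / fm.residual_variances["control"]
        true_ratio = (truth.residual_sd["mutant"] / truth.residual_sd["control"]) ** 2
        assert ratio == pytest.approx(true_ratio, rel=0.5)
        assert fm.residual_variances["mutant"] > fm.residual_variances["control"]

    def test_missing_weight_rows_dropped_only_for_weight_models(self, mm_phenlist):
        pl, _ = mm_phenlist
        frame = pl.frame.copy()
        frame.loc[frame.index[:5], "Weight"] = np.nan
        pl2 = replace_frame(pl, frame)
        fm_plain = fit_model(pl2, start_spec("response"))
        fm_weight = fit_model(pl2, start_spec("response", include_weight=True))
        assert fm_plain.n_used == len(pl2)
        assert fm_weight.n_used == len(pl2) - 5

    def test_singular_design_raises_fiterror(self, mm_phenlist):
        pl, _ = mm_phenlist
        frame = pl.frame.copy()
        frame["Weight"] = 7.0  # constant weight collinear with intercept
        with pytest.raises(FitError):
            fit_model(replace_frame(pl, frame), start_spec("response", include_weight=True))


def replace_frame(pl, frame):
    from phenokit.phenlist import PhenList

    return PhenList(
        frame=frame.reset_index(drop=True),
        test_genotype=pl.test_genotype, ref_genotype=pl.ref_genotype,
        variables=dict(pl.variables), cleaning_log=list(pl.cleaning_log),
    )


class TestStructureTests:
    def test_batch_detected_when_strong(self):
        pl, _ = synthetic_phenlist(SyntheticSpec(batch_sd=8.0, seed=13))
        significant, p = batch_significance_test(pl, start_spec("response"))
        assert significant and p < 0.01

    def test_batch_not_detected_when_absent(self):
        pl, _ = synthetic_phenlist(SyntheticSpec(batch_sd=0.0, seed=17))
        significant, p = batch_significance_test(pl, start_spec("response"))
        assert not significant

    def test_homogeneity_kept_on_equal_variances(self, mm_phenlist):
        pl, _ = mm_phenlist
        homogeneous, _ = variance_homogeneity_test(pl, start_spec("response"))
        assert homogeneous

    def test_heterogeneity_detected(self, het_phenlist):
        pl, _ = het_phenlist
        homogeneous, p = variance_homogeneity_test(pl, start_spec("response"))
        assert not homogeneous and p < 1e-6

    def test_mismatched_objectives_rejected(self, mm_phenlist):
        pl, _ = mm_phenlist
        full = start_spec("response")  # REML default
        reduced = replace(full.without("Genotype:Sex"), fit_objective="ML")
        with pytest.raises(ValueError, match="objective"):
            likelihood_ratio_test(pl, full, reduced, df=1)


class TestOptimisation:
    def test_null_structure_reduces_to_genotype_only_linear_model(self):
        spec = SyntheticSpec(
            batch_sd=0.0, sex_effect=0.0,
            genotype_effect={"male": -20.0, "female": -20.0},
            n_test={"male": 30, "female": 30}, seed=23,
        )
        pl, _ = synthetic_phenlist(spec)
        final, trace = optimise_model(pl, start_spec("response"))
        assert final.batch_role == "none"
        assert final.residual_variance == "homogeneous"
        assert "Genotype:Sex" not in final.fixed_terms
        assert "Genotype" in final.fixed_terms

    def test_weight_kept_when_it_drives_response(self):
        spec = SyntheticSpec(weight_slope=0.5, seed=29)
        pl, _ = synthetic_phenlist(spec)
        final, trace = optimise_model(pl, start_spec("response", include_weight=True))
        assert trace.weight_kept and trace.weight_p < 1e-4
        assert "Weight" in final.fixed_terms

    def test_weight_confound_story(self):
        # response driven purely by weight; genotype shifts weight, not response
        spec = SyntheticSpec(
            genotype_effect={"male": 0.0, "female": 0.0},
            weight_slope=0.8, batch_sd=2.0,
            n_test={"male": 20, "female": 20}, seed=31,
        )
        pl, truth = synthetic_phenlist(spec)
        # shift mutant weights (and hence responses) upward
        frame = pl.frame.copy()
        is_mut = frame["Genotype"] == "mutant"
        frame.loc[is_mut, "Weight"] += 40.0
        frame.loc[is_mut, "response"] += 0.8 * 40.0
        pl = replace_frame(pl, frame)
        res_plain = mm_analyse(pl, "response", include_weight=False)
        res_weight = mm_analyse(pl, "response", include_weight=True)
        assert res_plain.genotype_p < 0.05       # confounded: spurious hit
        assert res_weight.genotype_p > 0.05      # adjusted: effect vanishes


class TestGenotypeTestAndEffects:
    def test_strong_effect_detected(self, mm_phenlist):
        pl, _ = mm_phenlist
        final, _ = optimise_model(pl, start_spec("response"))
        assert genotype_test(pl, final) < 1e-4

    def test_equal_truth_gives_similar_per_sex_estimates(self):
        spec = SyntheticSpec(
            genotype_effect={"male": -20.0, "female": -20.0},
            n_test={"male": 40, "female": 40}, seed=37,
        )
        pl, _ = synthetic_phenlist(spec)
        fm = fit_model(pl, start_spec("response"))
        eff = estimate_effects(fm)
        pooled_se = np.hypot(eff.male[1], eff.female[1])
        assert abs(eff.male[0] - eff.female[0]) < 3 * pooled_se

    def test_combined_effect_reported_without_interaction(self, mm_phenlist):
        pl, _ = mm_phenlist
        fm = fit_model(pl, start_spec("response").without("Genotype:Sex"))
        eff = estimate_effects(fm)
        assert eff.combined is not None
        assert eff.male == eff.female == eff.combined


class TestClassification:
    @pytest.mark.parametrize(
        "p,male,female,kept,expected",
        [
            (0.5, (-10, 1), (-10, 1), True, "not significant"),
            (0.001, (-10, 1), (-10, 1), False, "both sexes equally"),
            (0.001, (-10, 1), (-5, 1), True, "different sizes — males greater"),
            (0.001, (-5, 1), (-10, 1), True, "different sizes — females greater"),
            (0.001, (-10, 1), (0.5, 1), True, "male only"),
            (0.001, (0.5, 1), (-10, 1), True, "female only"),
            (0.001, (-10, 1), (10, 1), True, "different directions"),
        ],
    )
    def test_closed_tag_set(self, p, male, female, kept, expected):
        eff = SexEffects(male=male, female=female)
        assert classify_effect(p, eff, kept) == expected

    def test_pipeline_classifies_dimorphic_screen(self):
        spec = SyntheticSpec(
            genotype_effect={"male": -26.0, "female": -16.0},
            n_test={"male": 30, "female": 30}, batch_sd=0.0, seed=41,
        )
        pl, _ = synthetic_phenlist(spec)
        res = mm_analyse(pl, "response")
        assert res.genotype_p < 1e-6
        assert res.classification_tag == "different sizes — males greater"
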