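"""Interaction regression: estimate recovery, sandwich errors, scaling,
genotype coding, the stratified reparametrization, and model invariances."""

import numpy as np
import pandas as pd
import pytest

from gxeartp.cohort import (
    DosagePanel,
    EffectSpec,
    simulate_cohort,
    simulate_dosages,
    synthetic_gene_snps,
)
from gxeartp.regression import (
    DegenerateFitError,
    ModelSpec,
    ScanDesign,
    build_design,
    dosage_to_genotype,
    fit_interaction,
    robust_interaction_scan,
    scale_to_iqr,
    scan_gene,
    stratified_exposure_fit,
)


def test_noise_free_fit_recovers_generating_betas(small_panel):
    cohort = simulate_cohort(small_panel, seed=7)
    eff = EffectSpec(
        beta_exposure=-0.01,
        beta_snp=1.5,
        beta_interaction=-0.03,
        target_snp_id="G1_snp3",
        covariate_betas={"age_followup": -0.05},
        noise_sd=1e-10,
        intercept=-4.0,
    )
    from gxeartp.cohort import simulate_outcomes

    cohort = simulate_outcomes(small_panel, cohort, eff, seed=7)
    res = fit_interaction(small_panel, cohort, "G1_snp3", ModelSpec())
    assert res.beta_snp == pytest.approx(1.5, abs=1e-6)
    assert res.beta_exposure == pytest.approx(-0.01, abs=1e-8)
    assert res.beta_interaction == pytest.approx(-0.03, abs=1e-8)


def test_sandwich_matches_explicit_matrix_algebra(small_panel, small_cohort, ratio_spec):
    """OLS betas and HC0 covariance against the closed-form (X'X)^-1 X'y and
    bread-meat-bread product, on a 50-row subset."""
    cohort = small_cohort.iloc[:50].reset_index(drop=True)
    panel = DosagePanel(
        individual_ids=small_panel.individual_ids[:50],
        snps=small_panel.snps,
        dosages=small_panel.dosages[:50],
    )
    res = fit_interaction(panel, cohort, "G1_snp2", ratio_spec)
    X, y = build_design(cohort, ratio_spec, panel.column("G1_snp2"))
    Xm, yv = X.to_numpy(float), y.to_numpy(float)
    bread = np.linalg.inv(Xm.T @ Xm)
    beta = bread @ Xm.T @ yv
    resid = yv - Xm @ beta
    meat = Xm.T @ (Xm * resid[:, None] ** 2)
    V = bread @ meat @ bread
    j = list(X.columns).index("snp_x_exposure")
    assert res.beta_interaction == pytest.approx(beta[j], rel=1e-9)
    assert res.se_interaction == pytest.approx(np.sqrt(V[j, j]), rel=1e-9)


def test_fast_scan_equals_statsmodels_per_snp(small_panel, small_cohort, ratio_spec):
    scan = robust_interaction_scan(small_cohort, ratio_spec, small_panel.dosages)
    for j, snp_id in enumerate(small_panel.snp_ids):
        ref = fit_interaction(small_panel, small_cohort, snp_id, ratio_spec)
        assert scan["beta_interaction"][j] == pytest.approx(ref.beta_interaction, rel=1e-9)
        assert scan["se_interaction"][j] == pytest.approx(ref.se_interaction, rel=1e-9)
        assert scan["p_interaction"][j] == pytest.approx(ref.p_interaction, rel=1e-6, abs=1e-12)


def test_robust_and_classical_ses_agree_under_homoskedasticity():
    specs = synthetic_gene_snps("g", "1", 1000, 1, mafs=[0.3])
    panel = simulate_dosages(5000, specs, seed=21)
    eff = EffectSpec(beta_snp=0.5, noise_sd=4.0, target_snp_id="g_snp1")
    cohort = simulate_cohort(panel, {"decline_ratio": eff}, seed=21)
    robust = fit_interaction(panel, cohort, "g_snp1", ModelSpec(), hc="HC0")
    import statsmodels.api as sm

    X, y = build_design(cohort, ModelSpec(), panel.column("g_snp1"))
    classical = sm.OLS(y, X).fit()
    assert robust.se_interaction == pytest.approx(
        classical.bse["snp_x_exposure"], rel=0.10
    )


class TestScaling:
    def test_identity_at_unit_iqr(self, small_panel, small_cohort, ratio_spec):
        res = fit_interaction(small_panel, small_cohort, "G1_snp1", ratio_spec)
        same = scale_to_iqr(res, 1.0)
        assert same.beta_interaction == res.beta_interaction

    def test_pm10_iqr_scaling_and_inverse(self, small_panel, small_cohort, ratio_spec):
        res = fit_interaction(small_panel, small_cohort, "G1_snp1", ratio_spec)
        scaled = scale_to_iqr(res, 83.4)
        assert scaled.beta_interaction == pytest.approx(res.beta_interaction * 83.4)
        assert scaled.se_exposure == pytest.approx(res.se_exposure * 83.4)
        assert scaled.p_interaction == res.p_interaction
        back = scale_to_iqr(scaled, 1 / 83.4)
        assert back.beta_interaction == pytest.approx(res.beta_interaction, rel=1e-12)

    def test_nonpositive_iqr_rejected(self, small_panel, small_cohort, ratio_spec):
        res = fit_interaction(small_panel, small_cohort, "G1_snp1", ratio_spec)
        with pytest.raises(ValueError):
            scale_to_iqr(res, 0.0)


class TestGenotypeCoding:
    @pytest.mark.parametrize(
        "dosage,code", [(0.0, 0), (0.49, 0), (0.5, 1), (1.49, 1), (1.5, 2), (2.0, 2)]
    )
    def test_thresholds(self, dosage, code):
        assert dosage_to_genotype(dosage) == code

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dosage_to_genotype(2.1)


class TestStratified:
    def test_reparametrized_model_matches_interaction_model_fits(self, small_panel, small_cohort, ratio_spec):
        """The carrier reparametrization spans the same column space as the
        binary-coded interaction model, so fitted values coincide."""
        import statsmodels.api as sm

        res = stratified_exposure_fit(
            small_panel, small_cohort, "G1_snp2", ratio_spec, keep_fitted=True
        )
        carrier = (dosage_to_genotype(small_panel.column("G1_snp2")) >= 1).astype(float)
        X, y = build_design(small_cohort, ratio_spec, dosage=None)
        X["carrier"] = carrier
        X["carrier_x_exposure"] = carrier * X[ratio_spec.exposure]
        standard = sm.OLS(y, X).fit()
        assert np.allclose(res.fitted_values, standard.fittedvalues, atol=1e-8)

    def test_cis_bracket_their_betas_and_strata_partition(self, small_panel, small_cohort, ratio_spec):
        res = stratified_exposure_fit(small_panel, small_cohort, "G1_snp2", ratio_spec)
        for b, lo, hi in zip(res.betas, res.ci_low, res.ci_high):
            assert lo < b < hi
        assert sum(res.n_per_stratum) == small_panel.n_individuals

    def test_equal_stratum_effects_give_null_interaction_p(self):
        # one large null cohort: the 1-df equality test should not reject strongly
        specs = synthetic_gene_snps("g", "1", 1000, 1, mafs=[0.4])
        panel = simulate_dosages(2000, specs, seed=31)
        cohort = simulate_cohort(panel, seed=31)
        res = stratified_exposure_fit(panel, cohort, "g_snp1", ModelSpec())
        assert res.p_interaction_1df > 0.001


class TestInvariances:
    def test_covariate_shift_leaves_interaction_unchanged(self, small_panel, small_cohort, ratio_spec):
        base = fit_interaction(small_panel, small_cohort, "G1_snp1", ratio_spec)
        shifted = small_cohort.copy()
        shifted["age_followup"] = shifted["age_followup"] + 100.0
        res = fit_interaction(small_panel, shifted, "G1_snp1", ratio_spec)
        assert res.beta_interaction == pytest.approx(base.beta_interaction, rel=1e-8)

    def test_allele_flip_negates_snp_terms_keeps_pvalues(self, small_panel, small_cohort, ratio_spec):
        base = fit_interaction(small_panel, small_cohort, "G1_snp1", ratio_spec)
        flipped = DosagePanel(
            individual_ids=small_panel.individual_ids,
            snps=small_panel.snps,
            dosages=2.0 - small_panel.dosages,
        )
        res = fit_interaction(flipped, small_cohort, "G1_snp1", ratio_spec)
        assert res.beta_snp == pytest.approx(-base.beta_snp, rel=1e-6)
        assert res.beta_interaction == pytest.approx(-base.beta_interaction, rel=1e-6)
        assert res.p_interaction == pytest.approx(base.p_interaction, rel=1e-6)

    def test_median_centering_changes_snp_not_interaction_beta(self, small_panel, small_cohort):
        plain = fit_interaction(small_panel, small_cohort, "G1_snp1", ModelSpec())
        centered = fit_interaction(
            small_panel, small_cohort, "G1_snp1",
            ModelSpec(center_exposure_at_median=True),
        )
        assert centered.beta_interaction == pytest.approx(plain.beta_interaction, rel=1e-8)
        assert centered.beta_snp != pytest.approx(plain.beta_snp, rel=1e-3)


class TestScanGene:
    def test_single_snp_gene_equals_direct_fit(self, small_panel, small_cohort, ratio_spec):
        results = scan_gene(small_panel, small_cohort, ["G1_snp1"], ratio_spec)
        direct = fit_interaction(small_panel, small_cohort, "G1_snp1", ratio_spec)
        assert len(results) == 1
        assert results[0].beta_interaction == direct.beta_interaction

    def test_duplicate_snps_give_identical_results(self, small_panel, small_cohort, ratio_spec):
        results = scan_gene(small_panel, small_cohort, ["G1_snp1", "G1_snp1"], ratio_spec)
        assert results[0].p_interaction == results[1].p_interaction

    def test_monomorphic_snp_recorded_not_raised(self, small_panel, small_cohort, ratio_spec):
        mono = DosagePanel(
            individual_ids=small_panel.individual_ids,
            snps=small_panel.snps,
            dosages=np.column_stack(
                [np.zeros(small_panel.n_individuals), small_panel.dosages[:, 1:]]
            ),
        )
        results = scan_gene(mono, small_cohort, ["G1_snp1", "G1_snp2"], ratio_spec)
        assert results[0].error is not None and "snp" in results[0].error
        assert results[1].error is None

    def test_degenerate_fit_names_collinear_columns(self, small_panel, small_cohort, ratio_spec):
        mono = DosagePanel(
            individual_ids=small_panel.individual_ids,
            snps=[small_panel.snps[0]],
            dosages=np.zeros((small_panel.n_individuals, 1)),
        )
        with pytest.raises(DegenerateFitError) as err:
            fit_interaction(mono, small_cohort, "G1_snp1", ratio_spec)
        assert any("snp" in c for c in err.value.columns)
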