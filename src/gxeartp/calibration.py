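"""End-to-end statistical calibration runs on synthetic cohorts.

These routines compose the synthetic-cohort generator, the robust interaction
scan and the ARTP permutation machinery into the standard frequentist checks a
new gene-environment pipeline owes its users: null p-value uniformity,
confidence-interval coverage for a planted interaction, and the empirical
type-I error of the gene-level ARTP test.  They are used both by the test
suite and by the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .artp import ArtpConfig, artp_unit_p, gene_permutation_store
from .cohort import EffectSpec, simulate_cohort, simulate_dosages, synthetic_gene_snps
from .regression import ModelSpec, ScanDesign

__all__ = [
    "null_interaction_pvalues",
    "interaction_ci_coverage",
    "artp_null_rejection_rate",
]


def _null_effect(outcome: str = "decline_ratio") -> EffectSpec:
    """Exposure and covariate effects only; no SNP main or interaction effect."""
    return EffectSpec(
        beta_exposure=-0.004,
        covariate_betas={
            "sex": 0.4,
            "age_followup": -0.05,
            "height_followup": 0.01,
            "packyears_baseline": -0.02,
        },
        noise_sd=4.0,
        intercept=-4.0,
    )


def _gene_snps(n_snps: int, imputed_every: int = 2):
    """MAFs spread over [0.05, 0.5]; every second SNP imputed at Rsq 0.6-0.95."""
    mafs = np.linspace(0.05, 0.5, n_snps)
    rsqs = [
        1.0 if j % imputed_every == 0 else 0.6 + 0.35 * (j / max(n_snps - 1, 1))
        for j in range(n_snps)
    ]
    return synthetic_gene_snps("GENE1", "1", 1_000_000, n_snps, mafs=mafs, rsqs=rsqs)


def null_interaction_pvalues(
    n: int = 650,
    n_snps: int = 1000,
    ld_rho: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Interaction p-values for many independent null SNPs in one cohort.

    The outcome depends on exposures and covariates but on no SNP, so the
    per-SNP interaction p-values should be uniform on (0, 1).
    """
    specs = _gene_snps(n_snps)
    if ld_rho == 0.0:
        # independent SNPs: put each on its own chromosome so no LD chain forms
        specs = [
            type(s)(
                snp_id=s.snp_id, chromosome=f"c{j}", position=s.position,
                allele1=s.allele1, allele2=s.allele2, maf=s.maf, rsq=s.rsq,
                genotyped=s.genotyped,
            )
            for j, s in enumerate(specs)
        ]
    panel = simulate_dosages(n, specs, ld_rho=ld_rho, seed=seed)
    cohort = simulate_cohort(panel, {"decline_ratio": _null_effect()}, seed=seed)
    spec = ModelSpec(outcome="decline_ratio", exposure="pm10_interval")
    return ScanDesign(cohort, spec).scan(panel.dosages)["p_interaction"]


def interaction_ci_coverage(
    beta_per_iqr: float = -3.8,
    iqr: float = 83.4,
    n: int = 650,
    n_reps: int = 200,
    maf: float = 0.3,
    seed: int = 0,
    level: float = 0.95,
) -> float:
    """Coverage of the robust 95% CI for a planted interaction effect.

    Each replicate simulates a cohort with a single SNP whose interaction with
    interval PM10 equals ``beta_per_iqr`` outcome units per allele per exposure
    IQR, fits the interaction model, and checks whether the IQR-scaled CI
    brackets the truth.  Returns the fraction of covering replicates.
    """
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    beta_natural = beta_per_iqr / iqr
    covered = 0
    for r in range(n_reps):
        rep_seed = (seed + 17 * r + 1) & 0x7FFFFFFF
        specs = synthetic_gene_snps("TGT", "1", 1_000_000, 1, mafs=[maf])
        panel = simulate_dosages(n, specs, seed=rep_seed)
        eff = _null_effect()
        eff = EffectSpec(
            beta_exposure=eff.beta_exposure,
            beta_snp=0.2,
            beta_interaction=beta_natural,
            target_snp_id="TGT_snp1",
            covariate_betas=eff.covariate_betas,
            noise_sd=eff.noise_sd,
            intercept=eff.intercept,
        )
        cohort = simulate_cohort(panel, {"decline_ratio": eff}, seed=rep_seed)
        spec = ModelSpec(outcome="decline_ratio", exposure="pm10_interval")
        scan = ScanDesign(cohort, spec).scan(panel.dosages)
        b = scan["beta_interaction"][0] * iqr
        se = scan["se_interaction"][0] * iqr
        if b - z * se <= beta_per_iqr <= b + z * se:
            covered += 1
    return covered / n_reps


def artp_null_rejection_rate(
    n_cohorts: int = 500,
    n: int = 650,
    n_snps: int = 20,
    ld_rho: float = 0.8,
    B: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical type-I error of the gene-level ARTP interaction test.

    Simulates independent null cohorts (LD-structured gene, exposure and
    covariate effects, zero interaction), runs the full regression +
    dosage-permutation ARTP pipeline on each, and returns the fraction of
    gene-level p-values below ``alpha``.
    """
    rejections = 0
    specs = _gene_snps(n_snps)
    spec = ModelSpec(outcome="decline_ratio", exposure="pm10_interval")
    for c in range(n_cohorts):
        rep_seed = (seed + 1009 * c + 3) & 0x7FFFFFFF
        panel = simulate_dosages(n, specs, ld_rho=ld_rho, seed=rep_seed)
        cohort = simulate_cohort(panel, {"decline_ratio": _null_effect()}, seed=rep_seed)
        design = ScanDesign(cohort, spec)
        config = ArtpConfig(n_permutations=B, seed=rep_seed)
        store = gene_permutation_store(design, panel.dosages, config)
        if artp_unit_p(store, config, unit_id="GENE1").p_artp < alpha:
            rejections += 1
    return rejections / n_cohorts
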