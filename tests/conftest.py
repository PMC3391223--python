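import numpy as np
import pytest

from gxeartp.cohort import (
    EffectSpec,
    simulate_cohort,
    simulate_dosages,
    synthetic_gene_snps,
)
from gxeartp.regression import ModelSpec


@pytest.fixture(scope="session")
def small_panel():
    """5-SNP LD gene, 300 individuals, mix of genotyped and imputed SNPs."""
    specs = synthetic_gene_snps(
        "G1", "1", 1_000_000, 5, mafs=[0.1, 0.2, 0.3, 0.4, 0.5], rsqs=[1.0, 0.8, 1.0, 0.9, 1.0]
    )
    return simulate_dosages(300, specs, ld_rho=0.5, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_panel):
    """Cohort with a planted interaction on FEV1/FVC decline at the first SNP."""
    eff = EffectSpec(
        beta_exposure=-0.004,
        beta_snp=0.3,
        beta_interaction=-0.02,
        target_snp_id="G1_snp1",
        covariate_betas={"sex": 0.4, "age_followup": -0.05},
        noise_sd=4.0,
        intercept=-4.0,
    )
    return simulate_cohort(small_panel, {"decline_ratio": eff}, seed=11)


@pytest.fixture(scope="session")
def ratio_spec():
    return ModelSpec(outcome="decline_ratio", exposure="pm10_interval")
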