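"""Synthetic cohorts for gene-environment interaction analysis of lung-function decline.

This module generates study populations with the statistical structure the
downstream analysis assumes: LD-structured imputed allele dosages, interval
air-pollution (PM10) and tobacco-smoking exposures with realistic marginal
distributions, standard epidemiological covariates, and 11-year spirometric
decline outcomes (FEV1, FEV1/FVC, FEF25-75) generated from a linear model with
configurable main and SNP-by-exposure interaction effects.

Genotypes are drawn from a latent first-order autocorrelated Gaussian per gene,
thresholded at the Hardy-Weinberg quantiles implied by each SNP's minor allele
frequency; this yields tunable, analytically checkable pairwise LD without a
reference haplotype panel.  Imputation noise is emulated by shrinking genotypes
toward their expectation and adding calibrated Gaussian noise so that the
squared correlation between dosage and true genotype equals the SNP's stated
imputation quality Rsq.

All randomness flows through a single integer seed; per-operation child seeds
are derived deterministically from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SnpSpec",
    "DosagePanel",
    "EffectSpec",
    "OUTCOME_COLUMNS",
    "COVARIATE_COLUMNS",
    "EXPOSURE_COLUMNS",
    "packyears",
    "hard_calls",
    "simulate_dosages",
    "simulate_exposures",
    "simulate_covariates",
    "simulate_outcomes",
    "simulate_cohort",
    "synthetic_gene_snps",
]

#: decline outcomes over the fixed 11-year interval (follow-up minus baseline)
OUTCOME_COLUMNS = ("decline_fev1", "decline_ratio", "decline_fef")

#: adjustment covariates of the interaction model
COVARIATE_COLUMNS = (
    "sex",
    "age_followup",
    "height_followup",
    "packyears_baseline",
    "pc1",
    "pc2",
    "pc3",
    "pc4",
    "study_area",
)

#: interval exposures accumulated between the two examinations
EXPOSURE_COLUMNS = ("pm10_interval", "packyears_interval")

_SMOKING_LEVELS = ("never", "former", "current")


def _child_rng(seed: int, *keys: int) -> np.random.Generator:
    """Deterministic per-operation generator derived from a single master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *keys]))


def packyears(cigarettes_per_day: float, years: float) -> float:
    """Packyears smoked: packs per day (cigarettes / 20) times years of exposure."""
    return cigarettes_per_day / 20.0 * years


@dataclass(frozen=True)
class SnpSpec:
    """Per-SNP metadata: identity, position, alleles, frequency and imputation quality.

    ``allele1`` is the effect allele whose expected count the dosage measures;
    ``maf`` is its frequency (minor, so in (0, 0.5]).  ``rsq`` is the imputation
    quality (squared dosage-genotype correlation); it is 1 for genotyped SNPs.
    """

    snp_id: str
    chromosome: str
    position: int
    allele1: str = "A"
    allele2: str = "G"
    maf: float = 0.2
    rsq: float = 1.0
    genotyped: bool = True

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValueError(f"{self.snp_id}: position must be positive")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"{self.snp_id}: maf must be in (0, 0.5], got {self.maf}")
        if not 0.0 < self.rsq <= 1.0:
            raise ValueError(f"{self.snp_id}: rsq must be in (0, 1], got {self.rsq}")
        if self.allele1 == self.allele2:
            raise ValueError(f"{self.snp_id}: alleles must differ")


@dataclass
class DosagePanel:
    """Individuals-by-SNPs matrix of expected effect-allele counts plus metadata.

    ``dosages`` has one row per individual and one column per SNP, entries in
    [0, 2] (NaN marks a missing call).  Column order matches ``snps``.
    """

    individual_ids: list[str]
    snps: list[SnpSpec]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, L = self.dosages.shape
        if n != len(self.individual_ids):
            raise ValueError("dosage rows must match individual_ids")
        if L != len(self.snps):
            raise ValueError("dosage columns must match snps")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual identifiers")
        if len({s.snp_id for s in self.snps}) != L:
            raise ValueError("duplicate SNP identifiers")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0.0) < 0 or np.nanmax(self.dosages, initial=0.0) > 2:
                raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def info(self) -> pd.DataFrame:
        """Per-SNP metadata as a data frame (column order mirrors the info file)."""
        return pd.DataFrame(
            {
                "snp_id": [s.snp_id for s in self.snps],
                "chromosome": [s.chromosome for s in self.snps],
                "position": [s.position for s in self.snps],
                "allele1": [s.allele1 for s in self.snps],
                "allele2": [s.allele2 for s in self.snps],
                "maf": [s.maf for s in self.snps],
                "rsq": [s.rsq for s in self.snps],
                "genotyped": [s.genotyped for s in self.snps],
            }
        )

    def column(self, snp_id: str) -> np.ndarray:
        """Dosage vector of one SNP."""
        try:
            j = self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"unknown SNP {snp_id!r}") from None
        return self.dosages[:, j]

    def subset(self, snp_ids: Sequence[str]) -> "DosagePanel":
        """Panel restricted to the given SNPs, in the given order."""
        index = {s: j for j, s in enumerate(self.snp_ids)}
        cols = [index[s] for s in snp_ids]
        return DosagePanel(
            individual_ids=list(self.individual_ids),
            snps=[self.snps[j] for j in cols],
            dosages=self.dosages[:, cols].copy(),
        )

    @staticmethod
    def concat(panels: Sequence["DosagePanel"]) -> "DosagePanel":
        """Column-wise concatenation of panels over the same individuals."""
        first = panels[0]
        for p in panels[1:]:
            if p.individual_ids != first.individual_ids:
                raise ValueError("panels must share identical individuals")
        return DosagePanel(
            individual_ids=list(first.individual_ids),
            snps=[s for p in panels for s in p.snps],
            dosages=np.hstack([p.dosages for p in panels]),
        )


@dataclass
class EffectSpec:
    """Linear-model coefficients used to generate a decline outcome.

    ``beta_interaction`` is in outcome units per effect allele per exposure
    unit (natural exposure scale, not IQR-scaled).  ``covariate_betas`` maps
    cohort column names to coefficients; unlisted covariates get 0.
    """

    beta_exposure: float = 0.0
    beta_snp: float = 0.0
    beta_interaction: float = 0.0
    target_snp_id: str | None = None
    covariate_betas: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 4.0
    intercept: float = -4.0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def hard_calls(dosages: np.ndarray) -> np.ndarray:
    """Round dosages to genotype counts by the 0.5 / 1.5 rule (NaN preserved)."""
    d = np.asarray(dosages, dtype=float)
    g = np.where(d < 0.5, 0.0, np.where(d < 1.5, 1.0, 2.0))
    return np.where(np.isnan(d), np.nan, g)


def _hwe_thresholds(maf: float) -> tuple[float, float]:
    """Latent-Gaussian cut points reproducing Hardy-Weinberg genotype frequencies."""
    lo = stats.norm.ppf((1.0 - maf) ** 2)
    hi = stats.norm.ppf(1.0 - maf**2)
    return lo, hi


def simulate_dosages(
    n: int,
    snp_specs: Sequence[SnpSpec],
    ld_rho: float = 0.0,
    seed: int = 0,
    id_prefix: str = "ind",
) -> DosagePanel:
    """Draw an LD-structured dosage panel for ``n`` individuals.

    A latent standard-normal variable follows a first-order autoregressive
    chain along the SNPs of each chromosome (correlation ``ld_rho`` between
    adjacent SNPs; the chain restarts when the chromosome label changes).  Each
    latent value is thresholded at the HWE quantiles implied by the SNP's minor
    allele frequency, giving genotypes 0/1/2 with the correct marginal
    distribution.  For imputed SNPs (``genotyped=False``) the dosage shrinks
    the genotype toward its expectation ``2*maf`` and adds calibrated noise so
    that corr(dosage, genotype)^2 equals ``rsq``; genotyped SNPs (or rsq=1)
    yield exact integer dosages.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    if not 0.0 <= ld_rho < 1.0:
        raise ValueError("ld_rho must be in [0, 1)")
    if not snp_specs:
        raise ValueError("need at least one SNP")
    rng = _child_rng(seed, 1)
    L = len(snp_specs)
    z = rng.standard_normal((n, L))
    carry = np.sqrt(1.0 - ld_rho**2)
    for j in range(1, L):
        if snp_specs[j].chromosome == snp_specs[j - 1].chromosome:
            z[:, j] = ld_rho * z[:, j - 1] + carry * z[:, j]
    dosages = np.empty((n, L))
    for j, spec in enumerate(snp_specs):
        lo, hi = _hwe_thresholds(spec.maf)
        g = (z[:, j] >= lo).astype(float) + (z[:, j] >= hi)
        if spec.genotyped or spec.rsq >= 1.0:
            dosages[:, j] = g
        else:
            mean = 2.0 * spec.maf
            sd_g = np.sqrt(2.0 * spec.maf * (1.0 - spec.maf))
            noise_sd = np.sqrt(spec.rsq * (1.0 - spec.rsq)) * sd_g
            d = mean + spec.rsq * (g - mean) + noise_sd * rng.standard_normal(n)
            dosages[:, j] = np.clip(d, 0.0, 2.0)
    ids = [f"{id_prefix}{i + 1:05d}" for i in range(n)]
    return DosagePanel(individual_ids=ids, snps=list(snp_specs), dosages=dosages)


def synthetic_gene_snps(
    gene: str,
    chromosome: str,
    start: int,
    n_snps: int,
    mafs: Sequence[float] | None = None,
    rsqs: Sequence[float] | None = None,
    spacing: int = 2000,
) -> list[SnpSpec]:
    """Evenly spaced SnpSpecs tiling one synthetic gene region."""
    if mafs is None:
        mafs = np.linspace(0.05, 0.5, n_snps)
    if rsqs is None:
        rsqs = [1.0] * n_snps
    return [
        SnpSpec(
            snp_id=f"{gene}_snp{j + 1}",
            chromosome=chromosome,
            position=start + j * spacing,
            maf=float(mafs[j]),
            rsq=float(rsqs[j]),
            genotyped=bool(rsqs[j] >= 1.0),
        )
        for j in range(n_snps)
    ]


def _lognormal_params(median: float, iqr: float) -> tuple[float, float]:
    # IQR/median = 2*sinh(z75*sigma) for a log-normal, z75 the 75% normal quantile
    z75 = stats.norm.ppf(0.75)
    sigma = np.arcsinh(iqr / (2.0 * median)) / z75
    return np.log(median), sigma


def simulate_exposures(
    n: int,
    pm10_median: float = 239.0,
    pm10_iqr: float = 83.4,
    smoking_mix: tuple[float, float, float] = (0.457, 0.308, 0.235),
    packyears_iqr: float = 9.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Interval exposures for ``n`` individuals.

    Interval PM10 (µg/m^3·years, the sum of annual mean home-outdoor PM10 over
    the 11 follow-up years) is log-normal, parameterized so its population
    median and IQR equal the targets; defaults reproduce the study sample
    (median 239.0, IQR 83.4).  Interval packyears are 0 for never smokers and
    most former smokers, and gamma-distributed for current smokers with the
    gamma scaled so the current-smoker IQR matches ``packyears_iqr``.

    Returns a data frame with columns ``smoking_status`` (never/former/current),
    ``pm10_interval`` and ``packyears_interval``.
    """
    mix = np.asarray(smoking_mix, dtype=float)
    if mix.shape != (3,) or np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError("smoking_mix must be three non-negative proportions summing to 1")
    if pm10_median <= 0 or pm10_iqr <= 0 or packyears_iqr <= 0:
        raise ValueError("medians and IQRs must be positive")
    rng = _child_rng(seed, 2)
    status = rng.choice(3, size=n, p=mix)

    mu, sigma = _lognormal_params(pm10_median, pm10_iqr)
    pm10 = np.exp(mu + sigma * rng.standard_normal(n))

    # gamma(shape=2): IQR = (q75 - q25) * scale with q75-q25 ~= 1.7316 shape units
    shape = 2.0
    unit_iqr = stats.gamma.ppf(0.75, shape) - stats.gamma.ppf(0.25, shape)
    scale = packyears_iqr / unit_iqr
    py = np.zeros(n)
    current = status == 2
    py[current] = rng.gamma(shape, scale, size=int(current.sum()))
    former = status == 1
    # most former smokers quit before baseline; a minority smoked into follow-up
    smoked_into_followup = former & (rng.random(n) < 0.25)
    py[smoked_into_followup] = rng.gamma(1.2, scale * 0.4, size=int(smoked_into_followup.sum()))

    return pd.DataFrame(
        {
            "smoking_status": pd.Categorical.from_codes(status, categories=list(_SMOKING_LEVELS)),
            "pm10_interval": pm10,
            "packyears_interval": py,
        }
    )


def simulate_covariates(
    n: int,
    smoking_status: Sequence[int] | pd.Categorical | None = None,
    n_pcs: int = 4,
    n_areas: int = 8,
    seed: int = 0,
) -> pd.DataFrame:
    """Adjustment covariates: sex, age and height at follow-up, baseline packyears,
    ancestry principal components, and study area.

    Sex and age are weakly correlated with smoking status (more male and
    slightly younger current smokers), echoing the descriptive patterns of a
    general-population cohort.  Ancestry PCs are standard normal; study area is
    uniform over ``n_areas`` labelled communities.
    """
    rng = _child_rng(seed, 3)
    if smoking_status is None:
        status = np.zeros(n, dtype=int)
    elif isinstance(smoking_status, pd.Series) and isinstance(
        smoking_status.dtype, pd.CategoricalDtype
    ):
        status = smoking_status.cat.codes.to_numpy()
    elif isinstance(smoking_status, pd.Categorical):
        status = np.asarray(smoking_status.codes)
    else:
        status = np.asarray(smoking_status, dtype=int)
    p_female = 0.55 - 0.03 * (status == 1) - 0.10 * (status == 2)
    sex = (rng.random(n) < p_female).astype(int)  # 1 = female
    age = np.clip(rng.normal(53.0, 9.0, n) - 1.5 * (status == 2), 29.0, 72.0)
    height = np.where(sex == 1, rng.normal(164.0, 6.5, n), rng.normal(176.5, 7.0, n))
    pk_base = np.where(status > 0, rng.gamma(2.0, 7.0, n), 0.0)
    out = pd.DataFrame(
        {
            "sex": sex,
            "age_followup": age,
            "height_followup": height,
            "packyears_baseline": pk_base,
        }
    )
    for k in range(n_pcs):
        out[f"pc{k + 1}"] = rng.standard_normal(n)
    out["study_area"] = pd.Categorical(
        [f"area{c + 1}" for c in rng.integers(0, n_areas, n)],
        categories=[f"area{a + 1}" for a in range(n_areas)],
    )
    return out


#: per-outcome generator defaults: (intercept, noise sd), in outcome units
_OUTCOME_DEFAULTS = {
    "decline_fev1": (-350.0, 250.0),  # ml over 11 years
    "decline_ratio": (-4.0, 4.0),  # FEV1/FVC percentage points
    "decline_fef": (-800.0, 550.0),  # ml/s
}


def simulate_outcomes(
    panel: DosagePanel,
    cohort: pd.DataFrame,
    spec: EffectSpec,
    seed: int = 0,
    outcome: str = "decline_ratio",
    exposure: str = "pm10_interval",
) -> pd.DataFrame:
    """Fill one decline outcome column from the interaction linear model.

    decline = intercept + covariates·betas + beta_exposure·E + beta_snp·G
              + beta_interaction·G·E + Gaussian noise.

    ``G`` is the dosage of ``spec.target_snp_id`` (zero if unset).  The decline
    is follow-up minus baseline, so losses are negative; a negative intercept
    makes the cohort decline on average.  Other outcome columns are untouched.
    """
    if outcome not in OUTCOME_COLUMNS:
        raise ValueError(f"unknown outcome {outcome!r}")
    rng = _child_rng(seed, 4)
    n = len(cohort)
    if panel.n_individuals != n:
        raise ValueError("panel and cohort sizes differ")
    e = cohort[exposure].to_numpy(dtype=float)
    y = np.full(n, float(spec.intercept))
    for col, beta in spec.covariate_betas.items():
        x = cohort[col]
        if isinstance(x.dtype, pd.CategoricalDtype):
            x = x.cat.codes
        y += float(beta) * x.to_numpy(dtype=float)
    y += spec.beta_exposure * e
    if spec.target_snp_id is not None:
        g = panel.column(spec.target_snp_id)
        y += spec.beta_snp * g + spec.beta_interaction * g * e
    y += spec.noise_sd * rng.standard_normal(n)
    out = cohort.copy()
    out[outcome] = y
    return out


def simulate_cohort(
    panel: DosagePanel,
    effect_specs: Mapping[str, EffectSpec] | None = None,
    exposure: str = "pm10_interval",
    pm10_median: float = 239.0,
    pm10_iqr: float = 83.4,
    smoking_mix: tuple[float, float, float] = (0.457, 0.308, 0.235),
    packyears_iqr: float = 9.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Full cohort table for a given dosage panel.

    ``effect_specs`` maps outcome column names to :class:`EffectSpec`; outcomes
    not listed are generated under the null (no SNP or interaction effect) with
    per-outcome default intercept and noise.  Covariates get small default
    effects (sex, age, height, baseline packyears) so adjustment matters.
    """
    n = panel.n_individuals
    exposures = simulate_exposures(
        n, pm10_median, pm10_iqr, smoking_mix, packyears_iqr, seed=seed
    )
    covars = simulate_covariates(n, exposures["smoking_status"], seed=seed)
    cohort = pd.concat([covars, exposures], axis=1)
    cohort.insert(0, "individual_id", panel.individual_ids)
    effect_specs = dict(effect_specs or {})
    for k, outcome in enumerate(OUTCOME_COLUMNS):
        intercept, noise_sd = _OUTCOME_DEFAULTS[outcome]
        spec = effect_specs.get(outcome)
        if spec is None:
            scale = abs(intercept) / 4.0
            spec = EffectSpec(
                beta_exposure=-0.001 * scale,
                covariate_betas={"sex": 0.05 * scale, "age_followup": -0.01 * scale},
                noise_sd=noise_sd,
                intercept=intercept,
            )
        cohort = simulate_outcomes(
            panel, cohort, spec, seed=seed + 1000 + k, outcome=outcome, exposure=exposure
        )
    return cohort
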