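"""Per-SNP gene-environment interaction regressions with robust standard errors.

The working model for each SNP and each outcome-exposure pair is ordinary
least squares

    decline = b0 + covariates + b_pm10*PM10 + b_py*packyears
              + b_snp*G + b_int*(G x E) + error

with an additive allele-dosage coding ``G``, both interval exposures always
included as main effects, one interaction term per fit, and
heteroskedasticity-consistent (Huber-White sandwich) standard errors.  Wald
p-values use the standard-normal reference by default, matching common GWAS
tooling; HC1 and the t reference are available by flag.

Two equivalent computational routes are provided: :func:`fit_interaction`
(statsmodels, one SNP at a time, full diagnostics) and
:func:`robust_interaction_scan` (a vectorized Frisch-Waugh-Lovell
implementation that scans many SNPs, and many permuted dosage panels, at once
for the permutation machinery).  Their agreement is enforced by the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import DosagePanel

__all__ = [
    "ModelSpec",
    "SnpInteractionResult",
    "StratifiedExposureResult",
    "DegenerateFitError",
    "build_design",
    "fit_interaction",
    "scale_to_iqr",
    "dosage_to_genotype",
    "genotype_label",
    "stratified_exposure_fit",
    "scan_gene",
    "robust_interaction_scan",
    "results_table",
]

#: default exposure IQRs on the natural exposure scale (PM10 µg/m^3·years, packyears)
DEFAULT_IQR = {"pm10_interval": 83.4, "packyears_interval": 9.8}

DEFAULT_COVARIATES = (
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


class DegenerateFitError(ValueError):
    """Raised when the design matrix is rank deficient (e.g. monomorphic SNP)."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(f"rank-deficient design; collinear columns: {self.columns}")


@dataclass(frozen=True)
class ModelSpec:
    """One outcome-exposure analysis configuration.

    ``exposure`` names the interaction partner; the other interval exposure
    stays in the model as a main effect.  ``iqr`` is the exposure contrast used
    when scaling effects (per-IQR reporting); ``center_exposure_at_median``
    median-centers the exposure before forming the interaction.
    """

    outcome: str = "decline_ratio"
    exposure: str = "pm10_interval"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    center_exposure_at_median: bool = False
    iqr: float | None = None

    def __post_init__(self) -> None:
        if self.exposure in self.covariates:
            raise ValueError("exposure must not also appear among covariates")
        if self.iqr is not None and self.iqr <= 0:
            raise ValueError("iqr must be positive when given")

    def exposure_iqr(self) -> float:
        return self.iqr if self.iqr is not None else DEFAULT_IQR[self.exposure]


@dataclass
class SnpInteractionResult:
    """Regression output for one SNP: betas, robust SEs, two-sided Wald p-values.

    When produced through IQR scaling, ``beta_interaction`` is in outcome units
    per effect allele per exposure IQR and ``beta_exposure`` per IQR.
    """

    snp_id: str
    n_used: int
    beta_snp: float
    beta_exposure: float
    beta_interaction: float
    se_snp: float
    se_exposure: float
    se_interaction: float
    p_snp: float
    p_exposure: float
    p_interaction: float
    iqr_scaled: bool = False
    error: str | None = None


@dataclass
class StratifiedExposureResult:
    """Genotype-stratum-specific exposure effects from one reparametrized model."""

    snp_id: str
    strata: tuple[str, str]
    betas: tuple[float, float]
    ci_low: tuple[float, float]
    ci_high: tuple[float, float]
    p_values: tuple[float, float]
    p_interaction_1df: float
    n_per_stratum: tuple[int, int]
    fitted_values: np.ndarray | None = None


def _expand_covariates(cohort: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Numeric covariate block; categoricals become indicator columns (first
    level, in sorted label order, is the reference)."""
    blocks = []
    for col in covariates:
        x = cohort[col]
        if isinstance(x.dtype, pd.CategoricalDtype) or x.dtype == object:
            levels = sorted(pd.unique(x.astype(str)))
            for lev in levels[1:]:
                blocks.append(pd.Series((x.astype(str) == lev).astype(float), name=f"{col}[{lev}]"))
        else:
            blocks.append(x.astype(float))
    return pd.concat(blocks, axis=1)


def build_design(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    dosage: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Design matrix and outcome for the interaction model.

    Columns, in order: intercept, covariates (categoricals expanded), both
    interval exposures, then — if a dosage is given — the SNP term and the
    SNP-by-exposure interaction.  The exposure is median-centered first when
    the spec requests it.
    """
    y = cohort[spec.outcome].astype(float)
    X = _expand_covariates(cohort, spec.covariates)
    for exp_col in ("pm10_interval", "packyears_interval"):
        e = cohort[exp_col].astype(float)
        if spec.center_exposure_at_median and exp_col == spec.exposure:
            e = e - e.median()
        X[exp_col] = e
    X.insert(0, "const", 1.0)
    if dosage is not None:
        X["snp"] = np.asarray(dosage, dtype=float)
        X["snp_x_exposure"] = X["snp"] * X[spec.exposure]
    return X, y


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    scale = np.linalg.norm(arr, axis=0)
    scale[scale == 0] = 1.0
    r = np.linalg.qr(arr / scale, mode="r")
    bad = np.abs(np.diag(r)) < 1e-8
    if bad.any():
        raise DegenerateFitError([X.columns[j] for j in np.flatnonzero(bad)])


def fit_interaction(
    panel: DosagePanel,
    cohort: pd.DataFrame,
    snp_id: str,
    spec: ModelSpec,
    hc: str = "HC0",
    use_t: bool = False,
) -> SnpInteractionResult:
    """Fit the interaction model for one SNP.

    OLS point estimates with sandwich (``HC0`` by default, ``HC1`` optional)
    standard errors; two-sided Wald p-values from the standard normal (or the
    residual-df t distribution when ``use_t``).  Complete cases only; a
    rank-deficient design raises :class:`DegenerateFitError` naming the
    collinear columns.
    """
    dosage = panel.column(snp_id)
    X, y = build_design(cohort, spec, dosage)
    mask = ~(X.isna().any(axis=1) | y.isna() | ~np.isfinite(X).all(axis=1))
    X, y = X[mask.to_numpy()], y[mask.to_numpy()]
    _check_rank(X)
    fit = sm.OLS(y, X).fit(cov_type=hc, use_t=use_t)
    return SnpInteractionResult(
        snp_id=snp_id,
        n_used=int(fit.nobs),
        beta_snp=float(fit.params["snp"]),
        beta_exposure=float(fit.params[spec.exposure]),
        beta_interaction=float(fit.params["snp_x_exposure"]),
        se_snp=float(fit.bse["snp"]),
        se_exposure=float(fit.bse[spec.exposure]),
        se_interaction=float(fit.bse["snp_x_exposure"]),
        p_snp=float(fit.pvalues["snp"]),
        p_exposure=float(fit.pvalues[spec.exposure]),
        p_interaction=float(fit.pvalues["snp_x_exposure"]),
    )


def scale_to_iqr(result: SnpInteractionResult, iqr: float) -> SnpInteractionResult:
    """Re-express exposure and interaction effects per one exposure IQR.

    Multiplies ``beta_exposure``, ``beta_interaction`` and their SEs by ``iqr``;
    p-values are scale-invariant and unchanged.
    """
    if iqr <= 0:
        raise ValueError("iqr must be positive")
    return replace(
        result,
        beta_exposure=result.beta_exposure * iqr,
        se_exposure=result.se_exposure * iqr,
        beta_interaction=result.beta_interaction * iqr,
        se_interaction=result.se_interaction * iqr,
        iqr_scaled=iqr != 1.0 or result.iqr_scaled,
    )


def dosage_to_genotype(dosage: float | np.ndarray) -> np.ndarray:
    """Hard genotype code from a dosage: <0.5 -> 0, [0.5, 1.5) -> 1, >=1.5 -> 2.

    Codes count copies of the effect allele; boundaries are inclusive below,
    exactly as used when contrasting imputed dosages with called genotypes.
    """
    d = np.asarray(dosage, dtype=float)
    if np.any((d < 0) | (d > 2)):
        raise ValueError("dosage out of [0, 2]")
    return np.where(d < 0.5, 0, np.where(d < 1.5, 1, 2)).astype(int)


def genotype_label(code: int, allele1: str, allele2: str) -> str:
    """Human-readable genotype from a 0/1/2 effect-allele count."""
    return {0: allele2 + allele2, 1: allele2 + allele1, 2: allele1 + allele1}[int(code)]


def stratified_exposure_fit(
    panel: DosagePanel,
    cohort: pd.DataFrame,
    snp_id: str,
    spec: ModelSpec,
    hc: str = "HC0",
    alpha: float = 0.05,
    keep_fitted: bool = False,
) -> StratifiedExposureResult:
    """Genotype-specific exposure effects via exposure reparametrization.

    A single model replaces the exposure main effect and interaction with a
    carrier indicator and two genotype-specific exposure columns (exposure
    restricted to baseline homozygotes vs to carriers of the effect allele),
    avoiding over-specification in small strata.  Per-stratum effects come with
    robust 95% CIs; ``p_interaction_1df`` is the robust Wald test of equality
    of the two exposure coefficients.  Spans the same column space as the
    standard interaction model with a binary carrier coding, so fitted values
    coincide.
    """
    geno = dosage_to_genotype(panel.column(snp_id))
    carrier = (geno >= 1).astype(float)
    n0, n1 = int((carrier == 0).sum()), int((carrier == 1).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("both genotype strata must be non-empty")
    X, y = build_design(cohort, spec, dosage=None)
    e = X.pop(spec.exposure)
    X["carrier"] = carrier
    X["exposure_wildtype"] = e * (1.0 - carrier)
    X["exposure_carrier"] = e * carrier
    _check_rank(X)
    fit = sm.OLS(y, X).fit(cov_type=hc, use_t=False)
    names = ["exposure_wildtype", "exposure_carrier"]
    betas = np.array([fit.params[n] for n in names])
    ses = np.array([fit.bse[n] for n in names])
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    pvals = 2.0 * stats.norm.sf(np.abs(betas / ses))
    contrast = np.zeros(X.shape[1])
    cols = list(X.columns)
    contrast[cols.index("exposure_carrier")] = 1.0
    contrast[cols.index("exposure_wildtype")] = -1.0
    var_diff = float(contrast @ fit.cov_params().to_numpy() @ contrast)
    z_diff = (betas[1] - betas[0]) / np.sqrt(var_diff)
    return StratifiedExposureResult(
        snp_id=snp_id,
        strata=("wild-type", "carrier"),
        betas=(float(betas[0]), float(betas[1])),
        ci_low=tuple(float(b - z * s) for b, s in zip(betas, ses)),
        ci_high=tuple(float(b + z * s) for b, s in zip(betas, ses)),
        p_values=(float(pvals[0]), float(pvals[1])),
        p_interaction_1df=float(2.0 * stats.norm.sf(abs(z_diff))),
        n_per_stratum=(n0, n1),
        fitted_values=np.asarray(fit.fittedvalues) if keep_fitted else None,
    )


def scan_gene(
    panel: DosagePanel,
    cohort: pd.DataFrame,
    gene_snp_list: Sequence[str],
    spec: ModelSpec,
    hc: str = "HC0",
) -> list[SnpInteractionResult]:
    """Fit every SNP of a gene in order; per-SNP failures are recorded, not raised."""
    results: list[SnpInteractionResult] = []
    for snp_id in gene_snp_list:
        try:
            results.append(fit_interaction(panel, cohort, snp_id, spec, hc=hc))
        except (DegenerateFitError, KeyError, ValueError) as exc:
            results.append(
                SnpInteractionResult(
                    snp_id=snp_id, n_used=0,
                    beta_snp=np.nan, beta_exposure=np.nan, beta_interaction=np.nan,
                    se_snp=np.nan, se_exposure=np.nan, se_interaction=np.nan,
                    p_snp=np.nan, p_exposure=np.nan, p_interaction=np.nan,
                    error=str(exc),
                )
            )
    return results


def results_table(results: Sequence[SnpInteractionResult], panel: DosagePanel | None = None) -> pd.DataFrame:
    """Tab-friendly table of per-SNP results (alleles/frequency added from panel)."""
    rows = []
    meta = {s.snp_id: s for s in panel.snps} if panel is not None else {}
    for r in results:
        m = meta.get(r.snp_id)
        rows.append(
            {
                "snp_id": r.snp_id,
                "chromosome": m.chromosome if m else "",
                "position": m.position if m else np.nan,
                "allele1": m.allele1 if m else "",
                "allele2": m.allele2 if m else "",
                "freq1": m.maf if m else np.nan,
                "n": r.n_used,
                "beta_interaction": r.beta_interaction,
                "se_interaction": r.se_interaction,
                "p_interaction": r.p_interaction,
                "beta_snp": r.beta_snp,
                "se_snp": r.se_snp,
                "p_snp": r.p_snp,
                "beta_exposure": r.beta_exposure,
                "se_exposure": r.se_exposure,
                "p_exposure": r.p_exposure,
                "error": r.error or "",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Vectorized scan used by the permutation machinery
# ---------------------------------------------------------------------------


class ScanDesign:
    """Precomputed fixed part of the interaction design for fast repeated scans.

    Holds an orthonormal basis of the non-SNP design block (intercept,
    covariates, both exposures) so that SNP and interaction columns can be
    residualized cheaply for every SNP and every dosage permutation.  The SNP
    coefficients and sandwich variances obtained through this
    Frisch-Waugh-Lovell route are algebraically identical to the full-design
    fit.
    """

    def __init__(self, cohort: pd.DataFrame, spec: ModelSpec):
        X, y = build_design(cohort, spec, dosage=None)
        self.spec = spec
        self.columns = list(X.columns)
        Z = X.to_numpy(dtype=float)
        self.n = Z.shape[0]
        self.Q, _ = np.linalg.qr(Z)
        e = X[spec.exposure].to_numpy(dtype=float)
        self.exposure = e
        yv = y.to_numpy(dtype=float)
        self.y_resid = yv - self.Q @ (self.Q.T @ yv)

    def scan(self, G: np.ndarray) -> dict[str, np.ndarray]:
        """Interaction scan over dosage matrices.

        ``G`` is (n, L) or a batch (B, n, L); returns arrays of shape (L,) or
        (B, L) with keys ``beta_snp``, ``beta_interaction``, ``se_interaction``,
        ``p_interaction``.  Degenerate columns give p = 1 (they carry no
        evidence and keep permutation p-vectors well defined).
        """
        G = np.asarray(G, dtype=float)
        squeeze = G.ndim == 2
        if squeeze:
            G = G[None]
        E = self.exposure
        GE = G * E[None, :, None]
        Q = self.Q
        X1 = G - Q @ (Q.T @ G)
        X2 = GE - Q @ (Q.T @ GE)
        y = self.y_resid
        c11 = np.einsum("bnl,bnl->bl", X1, X1)
        c12 = np.einsum("bnl,bnl->bl", X1, X2)
        c22 = np.einsum("bnl,bnl->bl", X2, X2)
        x1y = np.einsum("bnl,n->bl", X1, y)
        x2y = np.einsum("bnl,n->bl", X2, y)
        det = c11 * c22 - c12**2
        scale = np.maximum(c11 * c22, 1e-300)
        ok = det > 1e-12 * scale
        det_safe = np.where(ok, det, 1.0)
        beta1 = (c22 * x1y - c12 * x2y) / det_safe
        beta2 = (c11 * x2y - c12 * x1y) / det_safe
        resid = y[None, :, None] - X1 * beta1[:, None, :] - X2 * beta2[:, None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            u = X2 - X1 * np.where(c11 > 0, c12 / np.where(c11 > 0, c11, 1.0), 0.0)[:, None, :]
            uu = np.einsum("bnl,bnl->bl", u, u)
            meat = np.einsum("bnl,bnl->bl", u**2, resid**2)
            se2 = np.sqrt(meat) / np.where(uu > 0, uu, 1.0)
            zstat = np.abs(beta2) / np.where(se2 > 0, se2, np.inf)
        p = 2.0 * stats.norm.sf(zstat)
        p = np.where(ok, np.clip(p, np.finfo(float).tiny, 1.0), 1.0)
        out = {
            "beta_snp": np.where(ok, beta1, np.nan),
            "beta_interaction": np.where(ok, beta2, np.nan),
            "se_interaction": np.where(ok, se2, np.nan),
            "p_interaction": p,
        }
        if squeeze:
            out = {k: v[0] for k, v in out.items()}
        return out


def robust_interaction_scan(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    dosages: np.ndarray,
) -> dict[str, np.ndarray]:
    """Vectorized per-SNP interaction estimates over an (n, L) dosage matrix.

    Matches :func:`fit_interaction` (HC0, normal reference) column by column.
    """
    return ScanDesign(cohort, spec).scan(dosages)
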