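"""Publication-style summary tables for gene- and pathway-level results.

Multiple-testing control follows the analysis design exactly: Bonferroni at
the SNP level (m = number of analyzed SNPs), the gene level (m = number of
genes) and the pathway level (m = number of pathways), alongside the nominal
alpha = 0.05 exploratory view.  No false-discovery-rate view is added.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .artp import ArtpResult

__all__ = [
    "bonferroni_threshold",
    "nominal_gene_table",
    "exposure_contrast_report",
    "pathway_gene_profile",
]


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold controlling family-wise error over m tests."""
    if m < 1:
        raise ValueError("m must be at least 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


def nominal_gene_table(
    gene_results: Mapping[tuple[str, str], Mapping[str, ArtpResult]],
    alpha: float = 0.05,
    n_genes_tested: int | None = None,
) -> pd.DataFrame:
    """Genes with nominally significant interaction, per outcome-exposure stratum.

    ``gene_results`` maps (outcome, exposure) strata to per-gene ARTP results.
    Within each stratum, genes with p_artp < alpha are sorted ascending by
    p-value; strata with no such gene still appear (with an empty gene field)
    rather than being dropped.  Flags mark Bonferroni significance at the
    gene-test count and marginal significance (within a factor 2 of the
    Bonferroni threshold).
    """
    rows = []
    for (outcome, exposure), results in sorted(gene_results.items()):
        m = n_genes_tested or max(len(results), 1)
        bonf = bonferroni_threshold(alpha, m)
        hits = sorted(
            (r for r in results.values() if r.p_artp < alpha),
            key=lambda r: (r.p_artp, r.unit_id),
        )
        if not hits:
            rows.append(
                {
                    "outcome": outcome,
                    "exposure": exposure,
                    "gene": "",
                    "p_artp": np.nan,
                    "bonferroni_significant": False,
                    "marginally_significant": False,
                }
            )
            continue
        for r in hits:
            rows.append(
                {
                    "outcome": outcome,
                    "exposure": exposure,
                    "gene": r.unit_id,
                    "p_artp": r.p_artp,
                    "bonferroni_significant": r.p_artp < bonf,
                    "marginally_significant": bonf <= r.p_artp < 2.0 * bonf,
                }
            )
    return pd.DataFrame(rows)


def _strongest_snp(snp_table: pd.DataFrame) -> pd.Series:
    """Row with the smallest interaction p; ties break by genomic position."""
    t = snp_table.sort_values(["p_interaction", "position", "snp_id"], kind="mergesort")
    return t.iloc[0]


def exposure_contrast_report(
    snp_results_by_exposure: Mapping[str, pd.DataFrame],
    nominal_genes: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Side-by-side IQR-scaled effects of each gene's strongest interacting SNP.

    ``snp_results_by_exposure`` maps exposure name to a per-SNP results table
    (one row per SNP, columns as produced by ``results_table`` plus ``gene``);
    ``nominal_genes`` maps exposure name to the genes to report.  For each gene
    the SNP with the smallest interaction p-value under that exposure is
    selected (ties broken by position), mirroring the strongest-SNP contrast
    layout.
    """
    rows = []
    for exposure, genes in sorted(nominal_genes.items()):
        table = snp_results_by_exposure[exposure]
        for gene in genes:
            sub = table[table["gene"] == gene]
            if sub.empty:
                continue
            best = _strongest_snp(sub)
            rows.append(
                {
                    "exposure": exposure,
                    "gene": gene,
                    "snp_id": best["snp_id"],
                    "chromosome": best.get("chromosome", ""),
                    "position": best.get("position", np.nan),
                    "allele1": best.get("allele1", ""),
                    "allele2": best.get("allele2", ""),
                    "freq1": best.get("freq1", np.nan),
                    "n": best.get("n", np.nan),
                    "beta_interaction": best["beta_interaction"],
                    "se_interaction": best["se_interaction"],
                    "p_interaction": best["p_interaction"],
                    "beta_snp": best.get("beta_snp", np.nan),
                    "beta_exposure": best.get("beta_exposure", np.nan),
                }
            )
    return pd.DataFrame(rows)


def pathway_gene_profile(
    pathway: str,
    member_genes: Sequence[str],
    gene_results_by_exposure: Mapping[str, Mapping[str, ArtpResult]],
) -> pd.DataFrame:
    """Per-gene -log10 interaction p-values of one pathway, by exposure.

    Suitable for bar plotting.  Genes missing from a scan are listed with a
    missing marker (NaN and ``missing=True``); p-values at the permutation
    floor 1/(B+1) are flagged so maximal bars are not over-read.
    """
    rows = []
    for gene in member_genes:
        for exposure, results in sorted(gene_results_by_exposure.items()):
            r = results.get(gene)
            if r is None:
                rows.append(
                    {
                        "pathway": pathway,
                        "gene": gene,
                        "exposure": exposure,
                        "neg_log10_p": np.nan,
                        "at_floor": False,
                        "missing": True,
                    }
                )
            else:
                floor = 1.0 / (r.B_used + 1.0)
                rows.append(
                    {
                        "pathway": pathway,
                        "gene": gene,
                        "exposure": exposure,
                        "neg_log10_p": float(-np.log10(r.p_artp)),
                        "at_floor": bool(r.p_artp <= floor * (1 + 1e-12)),
                        "missing": False,
                    }
                )
    return pd.DataFrame(rows)
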