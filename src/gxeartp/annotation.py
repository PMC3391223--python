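"""Gene regions, SNP-to-gene and gene-to-pathway mapping, and SNP/sample QC.

Candidate genes are transcription spans flanked by 20 kb on each end; a SNP
belongs to every gene whose flanked interval contains its position (overlapping
loci such as EPX/LPO/MPO multi-map by design).  Coordinates are 1-based and
intervals inclusive on both ends throughout; 0-based starts must be shifted by
+1 at import.

QC follows standard imputed-GWAS practice: individuals with a low genotyping
success rate are dropped first, then SNPs failing Hardy-Weinberg equilibrium
(exact test on hard-called genotypes), call rate, minor allele frequency or
imputation quality are removed, each with an explicit reason in the exclusion
report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .cohort import DosagePanel, SnpSpec, hard_calls

__all__ = [
    "GeneRegion",
    "PathwayMap",
    "QcThresholds",
    "expand_region",
    "map_snps_to_genes",
    "hwe_exact_p",
    "qc_filter",
    "load_pathway_fixture",
    "load_gene_regions",
]

logger = logging.getLogger(__name__)

NOT_MAPPED = "NOT_MAPPED"


@dataclass(frozen=True)
class GeneRegion:
    """A gene's transcription span plus the symmetric flank added to each end."""

    gene_symbol: str
    chromosome: str
    tx_start: int
    tx_end: int
    flank: int = 20_000

    def __post_init__(self) -> None:
        if self.tx_start > self.tx_end:
            raise ValueError(f"{self.gene_symbol}: tx_start must not exceed tx_end")
        if self.flank < 0:
            raise ValueError("flank must be non-negative")


def expand_region(region: GeneRegion) -> tuple[str, int, int]:
    """Flanked interval (chromosome, start, end), inclusive, start clamped to 1."""
    start = max(1, region.tx_start - region.flank)
    return region.chromosome, start, region.tx_end + region.flank


def map_snps_to_genes(
    snps: list[SnpSpec], regions: list[GeneRegion]
) -> dict[str, list[str]]:
    """Map each gene to the position-sorted SNPs inside its flanked interval.

    SNPs may map to several overlapping genes; SNPs on a different chromosome
    never match.  Genes with no SNP are returned with an empty list.
    """
    out: dict[str, list[str]] = {}
    for region in regions:
        chrom, start, end = expand_region(region)
        hits = [
            s for s in snps if s.chromosome == chrom and start <= s.position <= end
        ]
        hits.sort(key=lambda s: (s.position, s.snp_id))
        out[region.gene_symbol] = [s.snp_id for s in hits]
    return out


def hwe_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact two-sided Hardy-Weinberg test probability.

    Conditional on the observed allele counts, enumerates every possible
    heterozygote count and sums the probabilities of all configurations no more
    likely than the observed one (the standard exact HWE test).  Monomorphic
    samples return 1.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotype required")
    n_a = 2 * n_aa + n_ab
    rare = min(n_a, 2 * n - n_a)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr
    # log P(het = h | n, allele counts), hypergeometric-type with 2^h pairings
    logp = (
        gammaln(n + 1)
        - gammaln(homr + 1)
        - gammaln(hets + 1)
        - gammaln(homc + 1)
        + hets * np.log(2.0)
    )
    logp -= logsumexp(logp)
    obs = np.searchsorted(hets, n_ab)
    if obs >= len(hets) or hets[obs] != n_ab:
        raise ValueError("heterozygote count inconsistent with allele counts")
    p = np.exp(logp[logp <= logp[obs] + 1e-12]).sum()
    return float(min(p, 1.0))


@dataclass(frozen=True)
class QcThresholds:
    """SNP and sample quality-control cut-offs (all open-interval fractions)."""

    hwe_p_min: float = 1e-4
    call_rate_min: float = 0.97
    maf_min: float = 0.05
    rsq_min: float = 0.5
    sample_call_rate_min: float = 0.97

    def __post_init__(self) -> None:
        for name in ("hwe_p_min", "call_rate_min", "maf_min", "rsq_min", "sample_call_rate_min"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")


def qc_filter(
    panel: DosagePanel, thresholds: QcThresholds = QcThresholds()
) -> tuple[DosagePanel, pd.DataFrame]:
    """Apply sample- then SNP-level QC; return the retained panel and a report.

    Individuals whose fraction of non-missing dosages falls below the sample
    call-rate threshold are removed first.  A SNP is then excluded if its exact
    HWE p-value (on 0.5/1.5 hard calls of non-missing dosages) is below
    ``hwe_p_min``, its call rate below ``call_rate_min``, its empirical minor
    allele frequency below ``maf_min``, or (for imputed SNPs) its imputation
    quality below ``rsq_min``.  The report lists one row per exclusion with all
    triggered rules.  Removing every SNP logs a warning rather than failing.
    """
    if panel.n_snps == 0 or panel.n_individuals == 0:
        raise ValueError("panel must be non-empty")
    records: list[dict] = []

    observed = ~np.isnan(panel.dosages)
    sample_cr = observed.mean(axis=1)
    keep_ind = sample_cr >= thresholds.sample_call_rate_min
    for i in np.flatnonzero(~keep_ind):
        records.append(
            {
                "unit": "sample",
                "id": panel.individual_ids[i],
                "reason": "sample_call_rate",
                "value": float(sample_cr[i]),
            }
        )
    dosages = panel.dosages[keep_ind]
    ids = [iid for iid, k in zip(panel.individual_ids, keep_ind) if k]

    keep_snp = np.ones(panel.n_snps, dtype=bool)
    for j, spec in enumerate(panel.snps):
        col = dosages[:, j]
        obs = ~np.isnan(col)
        reasons = []
        call_rate = float(obs.mean()) if len(col) else 0.0
        g = hard_calls(col[obs])
        counts = [int((g == k).sum()) for k in (0, 1, 2)]
        hwe_p = hwe_exact_p(*counts) if sum(counts) else 1.0
        freq1 = float(np.nanmean(col) / 2.0) if obs.any() else np.nan
        maf = min(freq1, 1.0 - freq1) if np.isfinite(freq1) else 0.0
        if hwe_p < thresholds.hwe_p_min:
            reasons.append("HWE")
        if call_rate < thresholds.call_rate_min:
            reasons.append("call_rate")
        if maf < thresholds.maf_min:
            reasons.append("MAF")
        if not spec.genotyped and spec.rsq < thresholds.rsq_min:
            reasons.append("Rsq")
        if reasons:
            keep_snp[j] = False
            records.append(
                {
                    "unit": "snp",
                    "id": spec.snp_id,
                    "reason": ",".join(reasons),
                    "value": maf,
                }
            )
    retained = DosagePanel(
        individual_ids=ids,
        snps=[s for s, k in zip(panel.snps, keep_snp) if k],
        dosages=dosages[:, keep_snp],
    ) if keep_snp.any() else None
    if retained is None:
        logger.warning("QC removed every SNP from the panel")
        retained = DosagePanel(individual_ids=ids, snps=[], dosages=np.empty((len(ids), 0)))
    report = pd.DataFrame(records, columns=["unit", "id", "reason", "value"])
    logger.info(
        "QC retained %d/%d individuals and %d/%d SNPs",
        len(ids), panel.n_individuals, int(keep_snp.sum()), panel.n_snps,
    )
    return retained, report


@dataclass
class PathwayMap:
    """Pathway-name to gene-symbol membership plus the explicit unmapped set."""

    pathways: dict[str, frozenset[str]]
    unmapped: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for name, genes in self.pathways.items():
            if not genes:
                raise ValueError(f"pathway {name!r} has no genes")

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set(self.unmapped)
        for genes in self.pathways.values():
            out |= genes
        return frozenset(out)

    def pathways_of(self, gene: str) -> list[str]:
        return sorted(name for name, genes in self.pathways.items() if gene in genes)


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("gxeartp").joinpath("data", name)))


def load_pathway_fixture(path: str | Path | None = None) -> PathwayMap:
    """Load the packaged oxidative-stress pathway membership table.

    The shipped fixture transcribes the 13 named molecular pathways of the
    candidate-gene panel plus the explicitly not-mapped gene set.  A
    user-supplied table with columns ``pathway`` and ``gene_symbol`` (for
    example, to add an apoptosis gene set) can be passed by path.
    """
    table = pd.read_csv(path or _fixture_path("pathways.tsv"), sep="\t")
    if not {"pathway", "gene_symbol"} <= set(table.columns):
        raise ValueError("pathway table needs columns 'pathway' and 'gene_symbol'")
    groups = table.groupby("pathway")["gene_symbol"].agg(frozenset).to_dict()
    unmapped = groups.pop(NOT_MAPPED, frozenset())
    pm = PathwayMap(pathways=groups, unmapped=unmapped)
    logger.info(
        "loaded %d pathways over %d genes (%d unmapped)",
        len(pm.pathways), len(pm.all_genes()), len(pm.unmapped),
    )
    return pm


def load_gene_regions(path: str | Path | None = None, flank: int = 20_000) -> list[GeneRegion]:
    """Load a gene-region table (gene_symbol, chromosome, tx_start, tx_end).

    Without a path this returns the packaged *synthetic* region fixture, whose
    coordinates are an invented deterministic layout of the candidate genes for
    simulation and demonstration; real transcription coordinates must be
    supplied by the user on matching 1-based coordinates.
    """
    table = pd.read_csv(path or _fixture_path("gene_regions_synthetic.tsv"), sep="\t")
    return [
        GeneRegion(
            gene_symbol=str(r.gene_symbol),
            chromosome=str(r.chromosome),
            tx_start=int(r.tx_start),
            tx_end=int(r.tx_end),
            flank=flank,
        )
        for r in table.itertuples()
    ]
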