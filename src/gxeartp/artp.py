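"""Adaptive Rank Truncation Product (ARTP) aggregation of interaction p-values.

The ARTP statistic combines the member p-values of a unit (the SNPs of a gene,
or the genes of a pathway) by multiplying the K smallest p-values at several
candidate truncation points K, adjusting each product against its permutation
distribution, and re-adjusting the minimum adjusted product to obtain a single
unit-level p-value.  The null distribution comes from permuting the rows
(individuals) of the unit's dosage matrix as a block — all SNP columns move
together, preserving within-gene LD while breaking the genotype-phenotype
link — and re-running the SNP-level interaction regressions on each permuted
panel.

All products are handled in log space; empirical p-values use the add-one
(B+1) estimator with ties counted as "<=", so every reported p lies in
[1/(B+1), 1] and is never exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import DosagePanel
from .regression import ModelSpec, ScanDesign

__all__ = [
    "ArtpConfig",
    "ArtpResult",
    "PermutationPvalueStore",
    "truncation_points",
    "log_truncated_product",
    "permutation_indices",
    "permute_panel",
    "adjusted_products",
    "artp_unit_p",
    "pathway_p",
    "gene_permutation_store",
    "run_gene_artp",
    "run_pathway_artp",
]

logger = logging.getLogger(__name__)

#: candidate truncation points before intersecting with [1, L]
_DEFAULT_CANDIDATES = (1, 2, 5, 10, 25)


@dataclass(frozen=True)
class ArtpConfig:
    """Permutation and truncation settings for ARTP.

    ``shared_permutations`` reuses one individual permutation for every gene at
    a given replicate, so inter-gene correlation survives to the pathway level;
    set it to False for per-gene independent permutations.
    """

    n_permutations: int = 10_000
    truncation_rule: str = "default"
    seed: int = 0
    shared_permutations: bool = True

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")


@dataclass
class ArtpResult:
    """Unit-level (gene or pathway) ARTP outcome with truncation diagnostics."""

    unit_id: str
    p_artp: float
    truncation_points: list[int]
    s_k: list[float]
    selected_k: int
    B_used: int
    n_members: int
    #: self-inclusive unit-level p for each permutation replicate (pathway input)
    permutation_p: np.ndarray | None = None


@dataclass
class PermutationPvalueStore:
    """Observed p-vector plus the B x L matrix of permutation p-vectors."""

    observed: np.ndarray
    perms: np.ndarray

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        self.perms = np.asarray(self.perms, dtype=float)
        if self.observed.ndim != 1 or self.perms.ndim != 2:
            raise ValueError("observed must be a vector and perms a matrix")
        if self.perms.shape[1] != self.observed.shape[0]:
            raise ValueError("permutation rows must match observed length")
        for arr in (self.observed, self.perms):
            if np.any(arr <= 0) or np.any(arr > 1):
                raise ValueError("p-values must lie in (0, 1]")

    @property
    def B(self) -> int:
        return self.perms.shape[0]

    @property
    def L(self) -> int:
        return self.observed.shape[0]


def truncation_points(L: int, rule: str = "default") -> list[int]:
    """Candidate truncation points for a unit with L members.

    The default rule takes {1, 2, 5, 10, 25, ceil(L/2), L}, intersects with
    [1, L], deduplicates and sorts.  The rule is pluggable by name.
    """
    if L < 1:
        raise ValueError("L must be at least 1")
    if rule == "default":
        cand = set(_DEFAULT_CANDIDATES) | {int(np.ceil(L / 2)), L}
        return sorted(k for k in cand if 1 <= k <= L)
    if rule == "all":
        return list(range(1, L + 1))
    raise ValueError(f"unknown truncation rule {rule!r}")


def log_truncated_product(pvals: Sequence[float], K: int) -> float:
    """Natural log of the product of the K smallest p-values (smaller = stronger)."""
    p = np.asarray(pvals, dtype=float)
    if not 1 <= K <= p.size:
        raise ValueError("K must be between 1 and the number of p-values")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return float(np.sort(np.log(p))[:K].sum())


def permutation_indices(n: int, replicate: int, config: ArtpConfig, key: int = 0) -> np.ndarray:
    """Row permutation for one replicate, a pure function of (seed, key, replicate).

    ``key`` distinguishes genes when permutations are not shared; with shared
    permutations it stays 0 so every gene sees the same individual shuffle.
    """
    if replicate < 1:
        raise ValueError("replicates are numbered from 1")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed & 0x7FFFFFFF, 7, key, replicate])
    )
    return rng.permutation(n)


def permute_panel(panel: DosagePanel, replicate: int, config: ArtpConfig, key: int = 0) -> DosagePanel:
    """Panel with individuals shuffled as a block (all SNP columns together).

    Phenotypes, exposures and covariates stay fixed; within-gene LD is exactly
    preserved because whole dosage rows move.
    """
    idx = permutation_indices(panel.n_individuals, replicate, config, key=key)
    return DosagePanel(
        individual_ids=list(panel.individual_ids),
        snps=list(panel.snps),
        dosages=panel.dosages[idx],
    )


def _log_products_matrix(pmat: np.ndarray, points: Sequence[int]) -> np.ndarray:
    """Row-wise log truncated products at each truncation point; pmat is (R, L)."""
    logs = np.sort(np.log(pmat), axis=1)
    cum = np.cumsum(logs, axis=1)
    return cum[:, np.asarray(points, dtype=int) - 1]


def _self_inclusive_rank(W: np.ndarray) -> np.ndarray:
    """Column-wise fraction of rows with value <= own (self counted)."""
    R = W.shape[0]
    out = np.empty_like(W)
    for k in range(W.shape[1]):
        order = np.sort(W[:, k])
        out[:, k] = np.searchsorted(order, W[:, k], side="right") / R
    return out


def adjusted_products(
    store: PermutationPvalueStore, points: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation-adjusted truncated products for the observed and each replicate.

    For every truncation point k, each row's log-product is ranked against all
    B+1 log-products at that point (itself included), giving
    s_k = #{rows with product <= own} / (B+1).  For the observed row this
    equals the add-one estimator (1 + #{permutations <= observed}) / (B+1).
    Returns (observed s_k vector of length m, B x m matrix for the replicates).
    """
    points = list(points)
    if max(points) > store.L or min(points) < 1:
        raise ValueError("truncation points out of range for the store")
    pmat = np.vstack([store.observed[None, :], store.perms])
    W = _log_products_matrix(pmat, points)
    s = _self_inclusive_rank(W)
    return s[0], s[1:]


def artp_unit_p(
    store: PermutationPvalueStore,
    config: ArtpConfig,
    unit_id: str = "unit",
    points: Sequence[int] | None = None,
) -> ArtpResult:
    """ARTP p-value for one unit from its permutation p-value store.

    The minimum adjusted product over truncation points is the unit statistic;
    its own permutation distribution re-adjusts it:
    p = (1 + #{replicates with MinP <= observed MinP}) / (B + 1).  The result
    carries the self-inclusive unit-level p for every replicate so the same
    procedure can be applied one level up (genes -> pathway).
    """
    if points is None:
        points = truncation_points(store.L, config.truncation_rule)
    s_obs, s_perm = adjusted_products(store, points)
    min_obs = float(s_obs.min())
    min_perm = s_perm.min(axis=1)
    B = store.B
    p = (1.0 + int((min_perm <= min_obs).sum())) / (B + 1.0)
    # self-inclusive unit p's across all rows, for the recursion to pathways
    all_min = np.concatenate([[min_obs], min_perm])
    order = np.sort(all_min)
    unit_p_all = np.searchsorted(order, all_min, side="right") / (B + 1.0)
    return ArtpResult(
        unit_id=unit_id,
        p_artp=float(p),
        truncation_points=list(points),
        s_k=[float(v) for v in s_obs],
        selected_k=int(points[int(np.argmin(s_obs))]),
        B_used=B,
        n_members=store.L,
        permutation_p=unit_p_all[1:],
    )


def pathway_p(
    gene_results: Mapping[str, ArtpResult],
    config: ArtpConfig,
    unit_id: str = "pathway",
) -> ArtpResult:
    """Pathway-level ARTP over member genes' observed and permutation p-values.

    All genes must share the same number of (aligned) permutation replicates;
    genes belonging to several pathways simply contribute to each.
    """
    genes = list(gene_results)
    if not genes:
        raise ValueError("pathway has no scanned genes")
    Bs = {gene_results[g].B_used for g in genes}
    if len(Bs) != 1:
        raise ValueError("gene results have misaligned permutation counts")
    observed = np.array([gene_results[g].p_artp for g in genes])
    perms = np.column_stack([gene_results[g].permutation_p for g in genes])
    store = PermutationPvalueStore(observed=observed, perms=perms)
    res = artp_unit_p(store, config, unit_id=unit_id)
    return res


def gene_permutation_store(
    design: ScanDesign,
    dosages: np.ndarray,
    config: ArtpConfig,
    key: int = 0,
    chunk: int = 64,
) -> PermutationPvalueStore:
    """Observed and permuted SNP interaction p-vectors for one gene.

    Re-runs the vectorized interaction scan on the observed dosage matrix and
    on ``config.n_permutations`` row-permuted copies (processed in chunks to
    bound memory).  The covariate/exposure design and outcome stay fixed; only
    dosages move.
    """
    G = np.asarray(dosages, dtype=float)
    n = G.shape[0]
    observed = design.scan(G)["p_interaction"]
    B = config.n_permutations
    perms = np.empty((B, G.shape[1]))
    for start in range(0, B, chunk):
        stop = min(start + chunk, B)
        idx = np.stack(
            [
                permutation_indices(n, b + 1, config, key=key)
                for b in range(start, stop)
            ]
        )
        perms[start:stop] = design.scan(G[idx])["p_interaction"]
    return PermutationPvalueStore(observed=observed, perms=perms)


def run_gene_artp(
    panel: DosagePanel,
    cohort: pd.DataFrame,
    gene_snp_map: Mapping[str, Sequence[str]],
    spec: ModelSpec,
    config: ArtpConfig,
) -> dict[str, ArtpResult]:
    """Gene-level ARTP for every gene with at least one SNP in the panel.

    With shared permutations every gene reuses the same individual shuffles per
    replicate (permutation key 0); otherwise each gene gets an independent
    stream keyed by its rank.  The full run is reproducible bit-for-bit from
    (data, spec, config).
    """
    design = ScanDesign(cohort, spec)
    results: dict[str, ArtpResult] = {}
    for rank, (gene, snp_ids) in enumerate(sorted(gene_snp_map.items())):
        snp_ids = [s for s in snp_ids if s in set(panel.snp_ids)]
        if not snp_ids:
            logger.info("gene %s has no SNPs in the panel; skipped", gene)
            continue
        sub = panel.subset(snp_ids)
        key = 0 if config.shared_permutations else rank + 1
        store = gene_permutation_store(design, sub.dosages, config, key=key)
        results[gene] = artp_unit_p(store, config, unit_id=gene)
        logger.debug("gene %s: p_artp=%.4g over %d SNPs", gene, results[gene].p_artp, len(snp_ids))
    return results


def run_pathway_artp(
    gene_results: Mapping[str, ArtpResult],
    pathway_genes: Mapping[str, Sequence[str]],
    config: ArtpConfig,
) -> dict[str, ArtpResult]:
    """Pathway-level ARTP for every pathway with at least one scanned gene."""
    out: dict[str, ArtpResult] = {}
    for pathway, genes in sorted(pathway_genes.items()):
        members = {g: gene_results[g] for g in genes if g in gene_results}
        if not members:
            logger.info("pathway %s has no scanned genes; skipped", pathway)
            continue
        out[pathway] = pathway_p(members, config, unit_id=pathway)
    return out


def artp_table(results: Mapping[str, ArtpResult]) -> pd.DataFrame:
    """Flat table of unit-level ARTP results."""
    return pd.DataFrame(
        [
            {
                "unit_id": r.unit_id,
                "n_members": r.n_members,
                "truncation_points": ",".join(map(str, r.truncation_points)),
                "s_k": ",".join(f"{v:.6g}" for v in r.s_k),
                "selected_k": r.selected_k,
                "p_artp": r.p_artp,
                "B": r.B_used,
            }
            for r in results.values()
        ]
    )
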