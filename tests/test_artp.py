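"""ARTP machinery: truncation points, truncated products, dosage permutation,
permutation-adjusted products, and the gene -> pathway recursion."""

import numpy as np
import pytest

from gxeartp.artp import (
    ArtpConfig,
    PermutationPvalueStore,
    adjusted_products,
    artp_unit_p,
    gene_permutation_store,
    log_truncated_product,
    pathway_p,
    permutation_indices,
    permute_panel,
    run_gene_artp,
    run_pathway_artp,
    truncation_points,
)
from gxeartp.cohort import simulate_cohort, simulate_dosages, synthetic_gene_snps
from gxeartp.regression import ModelSpec, ScanDesign


class TestTruncationPoints:
    @pytest.mark.parametrize(
        "L,expected",
        [
            (1, [1]),
            (7, [1, 2, 4, 5, 7]),
            (100, [1, 2, 5, 10, 25, 50, 100]),
            (3, [1, 2, 3]),
        ],
    )
    def test_default_rule(self, L, expected):
        assert truncation_points(L) == expected

    def test_invalid_length_rejected(self):
        with pytest.raises(ValueError):
            truncation_points(0)


class TestLogTruncatedProduct:
    def test_single_pvalue(self):
        assert log_truncated_product([0.5], 1) == pytest.approx(np.log(0.5))

    def test_two_smallest_of_three(self):
        assert log_truncated_product([0.01, 0.2, 0.9], 2) == pytest.approx(np.log(0.002))

    def test_closed_form_for_equal_pvalues(self):
        assert log_truncated_product([0.3] * 6, 6) == pytest.approx(6 * np.log(0.3))

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            log_truncated_product([0.0, 0.5], 1)
        with pytest.raises(ValueError):
            log_truncated_product([0.5], 2)


class TestPermutation:
    def test_pure_function_of_seed_and_replicate(self, small_panel):
        config = ArtpConfig(n_permutations=10, seed=3)
        a = permute_panel(small_panel, 4, config)
        b = permute_panel(small_panel, 4, config)
        assert np.array_equal(a.dosages, b.dosages)
        c = permute_panel(small_panel, 5, config)
        assert not np.array_equal(a.dosages, c.dosages)

    def test_rows_move_as_a_block(self, small_panel):
        config = ArtpConfig(n_permutations=10, seed=3)
        perm = permute_panel(small_panel, 1, config)
        # column means and the SNP-SNP correlation matrix are conserved
        assert np.allclose(perm.dosages.mean(axis=0), small_panel.dosages.mean(axis=0))
        assert np.allclose(
            np.corrcoef(perm.dosages.T), np.corrcoef(small_panel.dosages.T), atol=1e-12
        )

    def test_distinct_keys_decorrelate_genes(self, small_panel):
        config = ArtpConfig(n_permutations=10, seed=3, shared_permutations=False)
        i0 = permutation_indices(small_panel.n_individuals, 1, config, key=0)
        i1 = permutation_indices(small_panel.n_individuals, 1, config, key=1)
        assert not np.array_equal(i0, i1)


class TestAdjustedProducts:
    def test_hand_enumeration_at_three_permutations(self):
        store = PermutationPvalueStore(
            observed=np.array([0.1]),
            perms=np.array([[0.2], [0.05], [0.1]]),
        )
        s_obs, s_perm = adjusted_products(store, [1])
        # ranks among {0.1(obs), 0.2, 0.05, 0.1}: counts of values <= own, /4
        assert s_obs[0] == pytest.approx(3 / 4)
        assert s_perm[:, 0] == pytest.approx([1.0, 1 / 4, 3 / 4])

    def test_all_equal_products_rank_maximal(self):
        store = PermutationPvalueStore(
            observed=np.array([0.2, 0.2]), perms=np.full((5, 2), 0.2)
        )
        s_obs, s_perm = adjusted_products(store, [1, 2])
        assert np.all(s_obs == 1.0) and np.all(s_perm == 1.0)

    def test_dominant_observed_hits_the_floor(self):
        store = PermutationPvalueStore(
            observed=np.array([1e-6, 1e-6]),
            perms=np.random.default_rng(0).uniform(0.1, 1.0, size=(9, 2)),
        )
        s_obs, _ = adjusted_products(store, [1, 2])
        assert np.all(s_obs == pytest.approx(1 / 10))
        res = artp_unit_p(store, ArtpConfig(n_permutations=9))
        assert res.p_artp == pytest.approx(1 / 10)


class TestArtpUnit:
    def _null_store(self, rng, L=8, B=400, observed=None):
        perms = rng.uniform(size=(B, L))
        obs = rng.uniform(size=L) if observed is None else observed
        return PermutationPvalueStore(observed=obs, perms=perms)

    def test_p_bounded_by_permutation_floor(self):
        rng = np.random.default_rng(1)
        store = self._null_store(rng)
        res = artp_unit_p(store, ArtpConfig(n_permutations=store.B))
        assert 1 / (store.B + 1) <= res.p_artp <= 1.0

    def test_monotone_in_observed_pvalues(self):
        rng = np.random.default_rng(2)
        store = self._null_store(rng)
        base = artp_unit_p(store, ArtpConfig(n_permutations=store.B)).p_artp
        better = store.observed.copy()
        better[np.argmin(better)] = np.min(better) / 10
        res = artp_unit_p(
            PermutationPvalueStore(observed=better, perms=store.perms),
            ArtpConfig(n_permutations=store.B),
        ).p_artp
        assert res <= base

    def test_invariant_to_snp_order(self):
        rng = np.random.default_rng(3)
        store = self._null_store(rng)
        shuffle = rng.permutation(store.L)
        permuted = PermutationPvalueStore(
            observed=store.observed[shuffle], perms=store.perms[:, shuffle]
        )
        cfg = ArtpConfig(n_permutations=store.B)
        assert artp_unit_p(store, cfg).p_artp == artp_unit_p(permuted, cfg).p_artp

    def test_single_snp_gene_tracks_snp_pvalue(self):
        """With one SNP and truncation point 1, the ARTP p is the empirical
        rank of the SNP p among its permutation draws: Monte-Carlo consistent
        with the SNP-level p itself."""
        rng = np.random.default_rng(4)
        B = 1000
        estimates = []
        for _ in range(40):
            store = PermutationPvalueStore(
                observed=np.array([0.05]), perms=rng.uniform(size=(B, 1))
            )
            estimates.append(artp_unit_p(store, ArtpConfig(n_permutations=B)).p_artp)
        se = np.sqrt(0.05 * 0.95 / B)
        assert np.mean(estimates) == pytest.approx(0.05, abs=3 * se)


class TestPathway:
    def test_single_gene_pathway_equals_gene_p(self):
        rng = np.random.default_rng(5)
        store = PermutationPvalueStore(
            observed=rng.uniform(size=6), perms=rng.uniform(size=(300, 6))
        )
        cfg = ArtpConfig(n_permutations=300)
        gene = artp_unit_p(store, cfg, unit_id="G")
        pw = pathway_p({"G": gene}, cfg, unit_id="P")
        # one member, one truncation point: the readjustment is rank-preserving
        assert pw.p_artp == pytest.approx(gene.p_artp, abs=2 / 301)

    def test_misaligned_permutation_counts_rejected(self):
        rng = np.random.default_rng(6)
        cfg = ArtpConfig(n_permutations=100)
        g1 = artp_unit_p(
            PermutationPvalueStore(rng.uniform(size=3), rng.uniform(size=(100, 3))), cfg
        )
        cfg2 = ArtpConfig(n_permutations=50)
        g2 = artp_unit_p(
            PermutationPvalueStore(rng.uniform(size=3), rng.uniform(size=(50, 3))), cfg2
        )
        with pytest.raises(ValueError):
            pathway_p({"a": g1, "b": g2}, cfg)


class TestPipeline:
    def _study(self, seed=9, n=250):
        genes = {
            "GENEA": synthetic_gene_snps("GENEA", "1", 1_000_000, 4),
            "GENEB": synthetic_gene_snps("GENEB", "2", 2_000_000, 3),
        }
        from gxeartp.cohort import DosagePanel

        panels = [simulate_dosages(n, specs, ld_rho=0.6, seed=seed + i)
                  for i, specs in enumerate(genes.values())]
        panel = DosagePanel.concat(panels)
        cohort = simulate_cohort(panel, seed=seed)
        gene_map = {g: [s.snp_id for s in specs] for g, specs in genes.items()}
        return panel, cohort, gene_map

    def test_full_run_reproducible_bit_for_bit(self):
        panel, cohort, gene_map = self._study()
        spec = ModelSpec()
        cfg = ArtpConfig(n_permutations=50, seed=123)
        r1 = run_gene_artp(panel, cohort, gene_map, spec, cfg)
        r2 = run_gene_artp(panel, cohort, gene_map, spec, cfg)
        assert {g: r.p_artp for g, r in r1.items()} == {g: r.p_artp for g, r in r2.items()}
        p1 = run_pathway_artp(r1, {"PW": ["GENEA", "GENEB"]}, cfg)
        p2 = run_pathway_artp(r2, {"PW": ["GENEA", "GENEB"]}, cfg)
        assert p1["PW"].p_artp == p2["PW"].p_artp

    def test_planted_gene_signal_beats_null_gene(self):
        from gxeartp.cohort import EffectSpec, simulate_outcomes

        panel, cohort, gene_map = self._study(seed=13, n=500)
        eff = EffectSpec(
            beta_interaction=-0.04, target_snp_id="GENEA_snp2", noise_sd=4.0
        )
        cohort = simulate_outcomes(panel, cohort, eff, seed=13, outcome="decline_ratio")
        cfg = ArtpConfig(n_permutations=200, seed=7)
        res = run_gene_artp(panel, cohort, gene_map, ModelSpec(), cfg)
        assert res["GENEA"].p_artp < res["GENEB"].p_artp
        assert res["GENEA"].p_artp <= 0.05

    def test_store_shapes_and_observed_scan_consistency(self):
        panel, cohort, _ = self._study()
        spec = ModelSpec()
        design = ScanDesign(cohort, spec)
        cfg = ArtpConfig(n_permutations=30, seed=5)
        store = gene_permutation_store(design, panel.dosages, cfg)
        assert store.perms.shape == (30, panel.n_snps)
        direct = design.scan(panel.dosages)["p_interaction"]
        assert np.allclose(store.observed, direct)
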