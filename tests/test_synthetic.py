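"""Generator correctness: determinism, planted-truth consistency, and
recovery of planted parameters by the downstream estimators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from comolink import (
    SimulationConfig,
    nb_wald_de,
    pearson_matrix,
    simulate_association_catalog,
    simulate_coexpression_blocks,
    simulate_count_dataset,
    simulate_disease_pair,
    simulate_geneset_collection,
)
from comolink.variants import filter_associations


class TestCountDataset:
    def test_identical_seed_reproduces_bitwise(self):
        cfg = SimulationConfig(n_genes=200, seed=7)
        (a, ta), (b, tb) = simulate_count_dataset(cfg), simulate_count_dataset(cfg)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        assert ta.de_genes == tb.de_genes

    def test_no_planted_effects(self):
        cfg = SimulationConfig(n_genes=100, de_fraction=0.0, seed=3)
        _, truth = simulate_count_dataset(cfg)
        assert truth.de_genes == {}

    def test_planted_count_follows_rounding_rule(self):
        cfg = SimulationConfig(n_genes=1000, de_fraction=0.1, seed=0)
        _, truth = simulate_count_dataset(cfg)
        assert len(truth.de_genes) == 100

    def test_counts_are_nonnegative_integers(self):
        cm, _ = simulate_count_dataset(SimulationConfig(n_genes=50, seed=1))
        arr = cm.counts.to_numpy()
        assert np.issubdtype(arr.dtype, np.integer) and (arr >= 0).all()

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=0)
        with pytest.raises(ValueError):
            SimulationConfig(n_samples_per_group=0)
        with pytest.raises(ValueError):
            SimulationConfig(de_fraction=1.5)

    def test_planted_log2fc_recovered_on_average(self):
        """Wald log2FC estimates of planted genes center on the true +-2
        over 50 replicate simulations."""
        ests = []
        for seed in range(50):
            cm, truth = simulate_count_dataset(
                SimulationConfig(n_genes=400, n_samples_per_group=20, seed=seed)
            )
            de = nb_wald_de(cm).set_index("gene")
            for gene, lfc in truth.de_genes.items():
                ests.append(de.loc[gene, "log2fc"] * np.sign(lfc))
        assert abs(np.mean(ests) - 2.0) < 0.2

    def test_null_marginal_matches_configured_nb(self):
        """With no planted effects and a point baseline mean, pooled counts
        pass a chi-square GOF test against the configured NB at alpha 0.01."""
        mu, disp = 50.0, 0.1
        cfg = SimulationConfig(
            n_genes=1000, de_fraction=0.0, nb_mean_log_range=(mu, mu),
            nb_dispersion=disp, seed=42,
        )
        cm, _ = simulate_count_dataset(cfg)
        counts = cm.counts.to_numpy().ravel()
        size = 1.0 / disp
        p = size / (size + mu)
        hi = int(stats.nbinom.ppf(0.9995, size, p))
        edges = np.arange(hi + 1)
        expected = stats.nbinom.pmf(edges, size, p) * counts.size
        expected = np.append(expected, counts.size - expected.sum())  # right tail
        observed = np.bincount(np.minimum(counts, hi + 1), minlength=hi + 2).astype(float)
        keep = expected >= 5
        # merge sparse cells into the tail bucket
        obs = np.append(observed[keep][:-1], observed[~keep].sum() + observed[keep][-1])
        exp = np.append(expected[keep][:-1], expected[~keep].sum() + expected[keep][-1])
        stat, pval = stats.chisquare(obs, exp * obs.sum() / exp.sum())
        assert pval > 0.01


class TestDiseasePair:
    @pytest.mark.parametrize("shared_fraction,expected", [(0.0, 0), (0.5, 50), (1.0, 100)])
    def test_planted_shared_count(self, shared_fraction, expected):
        cfg_a = SimulationConfig(n_genes=1000, seed=1)
        cfg_b = SimulationConfig(n_genes=1000, seed=2)
        _, _, truth = simulate_disease_pair(cfg_a, cfg_b, shared_fraction)
        assert len(truth.shared_genes) == expected

    def test_shared_subset_of_both_planted_sets(self):
        cfg_a = SimulationConfig(n_genes=500, seed=5)
        cfg_b = SimulationConfig(n_genes=500, seed=6)
        _, _, truth = simulate_disease_pair(cfg_a, cfg_b, 0.4)
        de_a = set(truth.de_genes_by_dataset["A"])
        de_b = set(truth.de_genes_by_dataset["B"])
        assert truth.shared_genes <= de_a and truth.shared_genes <= de_b

    def test_full_overlap_equals_both_sets(self):
        cfg_a = SimulationConfig(n_genes=300, seed=8)
        cfg_b = SimulationConfig(n_genes=300, seed=9)
        _, _, truth = simulate_disease_pair(cfg_a, cfg_b, 1.0)
        assert truth.shared_genes == set(truth.de_genes_by_dataset["A"])
        assert truth.shared_genes == set(truth.de_genes_by_dataset["B"])

    def test_concordance_fraction_controls_signs(self):
        cfg_a = SimulationConfig(n_genes=500, seed=3)
        cfg_b = SimulationConfig(n_genes=500, seed=4)
        _, _, truth = simulate_disease_pair(cfg_a, cfg_b, 1.0, concordant_fraction=1.0)
        de_a, de_b = truth.de_genes_by_dataset["A"], truth.de_genes_by_dataset["B"]
        assert all(np.sign(de_a[g]) == np.sign(de_b[g]) for g in truth.shared_genes)
        _, _, t0 = simulate_disease_pair(cfg_a, cfg_b, 1.0, concordant_fraction=0.0)
        de_a, de_b = t0.de_genes_by_dataset["A"], t0.de_genes_by_dataset["B"]
        assert all(np.sign(de_a[g]) == -np.sign(de_b[g]) for g in t0.shared_genes)

    def test_shared_fraction_out_of_range(self):
        cfg = SimulationConfig(n_genes=100, seed=0)
        with pytest.raises(ValueError):
            simulate_disease_pair(cfg, cfg, 1.2)


class TestCoexpressionBlocks:
    def test_no_blocks_means_no_correlation_structure(self):
        cm, truth = simulate_coexpression_blocks(60, [], 0.9, 40, seed=2)
        assert truth.cluster_blocks == []
        corr, _ = pearson_matrix(cm, condition=None)
        off = corr.to_numpy()[np.triu_indices(corr.shape[0], k=1)]
        assert np.abs(off).max() < 0.7

    def test_blocks_are_disjoint_and_sized(self):
        _, truth = simulate_coexpression_blocks(100, [10, 20, 15], 0.8, 20, seed=1)
        sizes = sorted(len(b) for b in truth.cluster_blocks)
        assert sizes == [10, 15, 20]
        assert len(set().union(*truth.cluster_blocks)) == 45

    def test_within_block_correlation_reaches_factor_strength(self):
        cm, truth = simulate_coexpression_blocks(80, [20, 20], 0.9, 30, seed=5)
        corr, _ = pearson_matrix(cm, condition=None)
        for block in truth.cluster_blocks:
            idx = sorted(block)
            sub = corr.loc[idx, idx].to_numpy()
            tri = sub[np.triu_indices(len(idx), k=1)]
            assert tri.mean() > 0.8

    def test_block_separation_beats_background(self):
        """Min within-block correlation exceeds max between-block correlation
        in >=95% of 100 seeds (two blocks of 10 at strength 0.95)."""
        wins = 0
        for seed in range(100):
            cm, truth = simulate_coexpression_blocks(40, [10, 10], 0.95, 30, seed)
            corr, _ = pearson_matrix(cm, condition=None)
            b0, b1 = (sorted(b) for b in truth.cluster_blocks)
            within = min(
                corr.loc[b, b].to_numpy()[np.triu_indices(10, k=1)].min() for b in (b0, b1)
            )
            between = corr.loc[b0, b1].to_numpy().max()
            wins += within > between
        assert wins >= 95

    def test_invalid_factor_strength(self):
        with pytest.raises(ValueError):
            simulate_coexpression_blocks(50, [10], 1.5, 20, seed=0)


class TestAssociationCatalog:
    def test_exact_sub_threshold_count(self):
        records, truth = simulate_association_catalog(500, 40, seed=1)
        below = [r for r in records if r.p_value < 1e-5]
        assert len(below) == 40
        assert {r.gene_id for r in below} == truth.sub_threshold_assoc_genes
        assert filter_associations(records) == truth.sub_threshold_assoc_genes

    def test_zero_significant(self):
        records, _ = simulate_association_catalog(50, 0, seed=2)
        assert filter_associations(records) == set()

    def test_two_source_union_semantics(self):
        ra, ta = simulate_association_catalog(100, 10, seed=3, trait="obesity")
        rb, tb = simulate_association_catalog(100, 15, seed=4, trait="obesity")
        pooled = filter_associations(ra + rb)
        assert pooled == ta.sub_threshold_assoc_genes | tb.sub_threshold_assoc_genes

    def test_invalid_p_floor(self):
        with pytest.raises(ValueError):
            simulate_association_catalog(10, 2, p_floor=0.0)


class TestGenesetCollection:
    def test_members_within_universe_and_sizes(self):
        universe = [f"G{i:04d}" for i in range(1, 501)]
        coll, _ = simulate_geneset_collection(universe, 20, (10, 30), seed=1)
        for members in coll.terms.values():
            assert 10 <= len(members) <= 30
            assert members <= set(universe)

    def test_planted_term_oversamples_query(self):
        universe = [f"G{i:04d}" for i in range(1, 1001)]
        query = set(universe[:100])
        coll, truth = simulate_geneset_collection(
            universe, 10, (50, 50), planted={"TERM_0001": 0.8}, seed=2, query=query
        )
        assert truth.enriched_terms == {"TERM_0001"}
        assert len(coll.terms["TERM_0001"] & query) == 40

    def test_planting_requires_query(self):
        with pytest.raises(ValueError):
            simulate_geneset_collection(["A", "B", "C"], 2, (1, 2), planted={"T": 0.5})

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            simulate_geneset_collection([], 5, (1, 2))
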