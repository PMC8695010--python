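"""Coexpression network: adjacency, scale-free fit, TOM, module detection."""
import dataclasses

import numpy as np
import pandas as pd
import pytest

import dysmod
from dysmod import network
from dysmod.datatypes import GRAY

from conftest import make_matrix


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    """Triple-loop evaluation of the unsigned TOM formula (oracle)."""
    n = a.shape[0]
    k = a.sum(axis=1) - 1.0
    tom = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


def random_adjacency(rng, n):
    r = rng.uniform(0, 1, size=(n, n))
    a = (r + r.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return a


class TestCorrelationMatrix:
    def test_exact_collinearity(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        vals = np.vstack([x, 2 * x, x[::-1]])
        m = make_matrix(vals, 2, 2)
        r = network.correlation_matrix(m)
        assert r.iloc[0, 0] == 1.0
        assert r.iloc[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert r.iloc[0, 2] == pytest.approx(-1.0, abs=1e-12)

    def test_constant_gene_excluded_with_warning(self, caplog):
        vals = np.vstack([np.ones(5), np.arange(5.0), np.arange(5.0)[::-1]])
        m = make_matrix(vals, 3, 2)
        with caplog.at_level("WARNING"):
            r = network.correlation_matrix(m)
        assert r.shape == (2, 2)
        assert "constant" in caplog.text

    def test_too_few_samples_rejected(self):
        m = make_matrix(np.random.default_rng(0).normal(size=(5, 2)), 1, 1)
        with pytest.raises(ValueError):
            network.correlation_matrix(m)


class TestScaleFreeFit:
    def test_exact_power_law_histogram_gives_unit_r2(self):
        # values 1, 2, 4 in three distinct equal-width bins with counts
        # proportional to 1/k: log-log points are exactly collinear
        k = np.concatenate([np.full(16, 1.0), np.full(8, 2.0), np.full(4, 4.0)])
        assert network.scale_free_fit(k, n_bins=3) == pytest.approx(1.0, abs=1e-12)

    def test_constant_connectivity_rejected(self):
        with pytest.raises(ValueError):
            network.scale_free_fit(np.full(100, 3.0), n_bins=10)

    def test_poisson_like_degree_distribution_is_not_scale_free(self):
        rng = np.random.default_rng(8)
        k = rng.binomial(500, 0.1, size=2000).astype(float)
        assert network.scale_free_fit(k, n_bins=10) < 0.5


class TestSoftThreshold:
    def test_power_one_is_identity_on_absolute_correlation(self):
        rng = np.random.default_rng(9)
        m = make_matrix(rng.normal(size=(20, 10)), 5, 5)
        r = network.correlation_matrix(m)
        a = network.adjacency_from_correlation(r, beta=1)
        np.testing.assert_allclose(a.to_numpy(), np.abs(r.to_numpy()), atol=1e-15)

    def test_adjacency_strictly_decreases_with_power(self):
        rng = np.random.default_rng(10)
        m = make_matrix(rng.normal(size=(15, 8)), 4, 4)
        r = network.correlation_matrix(m)
        a2 = network.adjacency_from_correlation(r, 2).to_numpy()
        a3 = network.adjacency_from_correlation(r, 3).to_numpy()
        off = ~np.eye(15, dtype=bool)
        strict = (np.abs(r.to_numpy()) > 0) & (np.abs(r.to_numpy()) < 1) & off
        assert (a3[strict] < a2[strict]).all()

    def test_planted_modules_select_moderate_power(self, small_config):
        cfg = dataclasses.replace(small_config, de_fraction=0.0)
        m, _ = dysmod.generate_expression(cfg)
        soft = network.pick_soft_threshold(m)
        assert soft.beta <= 12
        assert set(soft.fit_r2_by_power) == set(network.DEFAULT_POWERS)


class TestTopologicalOverlap:
    def test_two_gene_closed_form(self):
        a = np.array([[1.0, 0.3], [0.3, 1.0]])
        tom = network.topological_overlap(pd.DataFrame(a, index=["a", "b"], columns=["a", "b"]))
        assert tom.iloc[0, 1] == pytest.approx(0.3, abs=1e-12)

    def test_complete_graph_closed_form(self):
        n = 6
        a = pd.DataFrame(np.ones((n, n)))
        tom = network.topological_overlap(a)
        np.testing.assert_allclose(tom.to_numpy(), 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 13)
        a = random_adjacency(rng, n)
        tom = network.topological_overlap(pd.DataFrame(a)).to_numpy()
        expected = brute_force_tom(a)
        np.testing.assert_allclose(tom, expected, atol=1e-12)
        assert tom.min() >= 0 and tom.max() <= 1


class TestDetectModules:
    def test_two_noiseless_blocks_recovered_exactly(self):
        cfg = dysmod.SimulationConfig(
            n_genes=80, n_case=15, n_control=15, module_sizes=(40, 40),
            loading=1.0, noise_sd=0.0, de_fraction=0.0, seed=11,
        )
        m, truth = dysmod.generate_expression(cfg)
        r = network.correlation_matrix(m)
        tom = network.topological_overlap(network.adjacency_from_correlation(r, 6))
        part = network.detect_modules(tom, min_module_size=10)
        assert len(part.modules) == 2
        from sklearn.metrics import adjusted_rand_score

        truth_labels = [str(truth.module_of_gene[g]) for g in part.gene_ids]
        pred = [str(x) for x in part.module_of_gene]
        assert adjusted_rand_score(truth_labels, pred) == 1.0

    def test_pure_noise_goes_gray(self):
        rng = np.random.default_rng(12)
        m = make_matrix(rng.normal(size=(500, 100)), 50, 50)
        r = network.correlation_matrix(m)
        soft = network.pick_soft_threshold(m, r=r)
        tom = network.topological_overlap(network.adjacency_from_correlation(r, soft.beta))
        part = network.detect_modules(tom)
        assert part.n_gray >= 0.9 * 500

    def test_oversized_min_module_size_makes_everything_gray(self):
        rng = np.random.default_rng(13)
        a = random_adjacency(rng, 20)
        tom = network.topological_overlap(pd.DataFrame(a))
        part = network.detect_modules(tom, min_module_size=50)
        assert part.n_gray == 20 and part.modules == []

    def test_partition_invariant_to_gene_order(self, small_config):
        m, _ = dysmod.generate_expression(small_config)
        r = network.correlation_matrix(m)
        tom = network.topological_overlap(network.adjacency_from_correlation(r, 6))
        part = network.detect_modules(tom)
        rng = np.random.default_rng(14)
        perm = rng.permutation(len(tom))
        tom_p = tom.iloc[perm, perm]
        part_p = network.detect_modules(tom_p)
        from sklearn.metrics import adjusted_rand_score

        joint = pd.concat(
            [part.module_of_gene.rename("a"), part_p.module_of_gene.rename("b")], axis=1
        )
        assert adjusted_rand_score(joint["a"].astype(str), joint["b"].astype(str)) == 1.0


class TestEigengenesAndHubs:
    def _partition(self, labels, genes):
        return dysmod.ModulePartition(pd.Series(labels, index=genes, dtype=object))

    def test_rank_one_module_eigengene_is_the_standardized_profile(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        vals = np.vstack([profile] * 4)
        m = make_matrix(vals, 3, 3)
        part = self._partition([1] * 4, m.gene_ids)
        part = network.module_eigengenes(m, part)
        expected = (profile - profile.mean()) / profile.std(ddof=1)
        me = part.eigengenes.loc[1].to_numpy()
        np.testing.assert_allclose(me, expected, atol=1e-10)
        assert part.variance_explained[1] == pytest.approx(1.0)

    def test_sign_orientation_gives_nonnegative_mean_correlation(self, small_config):
        m, truth = dysmod.generate_expression(small_config)
        labels = [truth.module_of_gene[g] for g in m.gene_ids]
        part = self._partition(
            [x if x != "background" else GRAY for x in labels], m.gene_ids
        )
        part = network.module_eigengenes(m, part)
        for mod in part.modules:
            me = part.eigengenes.loc[mod].to_numpy()
            cors = [
                np.corrcoef(m.values.loc[g].to_numpy(), me)[0, 1] for g in part.genes_in(mod)
            ]
            assert np.mean(cors) >= 0

    def test_eigengene_tracks_latent_factor(self):
        cfg = dysmod.SimulationConfig(
            n_genes=100, n_case=40, n_control=40, module_sizes=(60,),
            loading=0.9, noise_sd=0.3, de_fraction=0.0, seed=15,
        )
        m, truth = dysmod.generate_expression(cfg)
        part = self._partition(
            [truth.module_of_gene[g] if truth.module_of_gene[g] != "background" else GRAY
             for g in m.gene_ids],
            m.gene_ids,
        )
        part = network.module_eigengenes(m, part)
        f = truth.latent_factors.loc[1].to_numpy()
        me = part.eigengenes.loc[1].to_numpy()
        assert np.corrcoef(f, me)[0, 1] ** 2 >= 0.8

    def test_rank_one_module_hub_tie_breaks_lexicographically(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        m = make_matrix(np.vstack([profile] * 3), 3, 3)
        part = self._partition([1] * 3, m.gene_ids)
        part = network.hub_genes(m, network.module_eigengenes(m, part))
        assert part.hub_gene[1] == min(m.gene_ids)

    def test_hub_gene_belongs_to_its_module(self, small_config):
        m, _ = dysmod.generate_expression(small_config)
        r = network.correlation_matrix(m)
        tom = network.topological_overlap(network.adjacency_from_correlation(r, 6))
        part = network.detect_modules(tom)
        part = network.hub_genes(m, network.module_eigengenes(m, part))
        for mod, hub in part.hub_gene.items():
            assert hub in part.genes_in(mod)

    def test_strongest_loading_gene_is_usually_the_hub(self):
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(200 + seed)
            f = rng.standard_normal(100)
            vals = np.vstack(
                [1.0 * f + rng.normal(0, 0.3, 100)]
                + [0.6 * f + rng.normal(0, 0.3, 100) for _ in range(9)]
            )
            m = make_matrix(vals, 50, 50)
            part = self._partition([1] * 10, m.gene_ids)
            part = network.hub_genes(m, network.module_eigengenes(m, part))
            wins += part.hub_gene[1] == m.gene_ids[0]
        assert wins >= 95


class TestModuleRelationshipNetwork:
    def test_shared_latent_factor_creates_a_strong_edge(self):
        cfg = dysmod.SimulationConfig(
            n_genes=120, n_case=50, n_control=50, module_sizes=(50, 50),
            loading=0.9, noise_sd=0.3, de_fraction=0.0,
            shared_factor_pairs=((1, 2),), seed=16,
        )
        m, truth = dysmod.generate_expression(cfg)
        part = dysmod.ModulePartition(
            pd.Series(
                [truth.module_of_gene[g] if truth.module_of_gene[g] != "background" else GRAY
                 for g in m.gene_ids],
                index=m.gene_ids, dtype=object,
            )
        )
        part = network.module_eigengenes(m, part)
        edges = network.module_relationship_network(part, 0.5)
        assert len(edges) == 1
        assert abs(edges.iloc[0]["cor"]) > 0.9

    def test_independent_modules_rarely_connect_at_half_cut(self):
        connected = 0
        for seed in range(20):
            cfg = dysmod.SimulationConfig(
                n_genes=100, n_case=90, n_control=90, module_sizes=(40, 40),
                de_fraction=0.0, seed=300 + seed,
            )
            m, truth = dysmod.generate_expression(cfg)
            part = dysmod.ModulePartition(
                pd.Series(
                    [truth.module_of_gene[g] if truth.module_of_gene[g] != "background"
                     else GRAY for g in m.gene_ids],
                    index=m.gene_ids, dtype=object,
                )
            )
            part = network.module_eigengenes(m, part)
            connected += len(network.module_relationship_network(part, 0.5)) > 0
        assert connected <= 1  # >= 95% of replicates edge-free

    def test_zero_cut_yields_complete_graph(self, small_config):
        m, truth = dysmod.generate_expression(small_config)
        part = dysmod.ModulePartition(
            pd.Series(
                [truth.module_of_gene[g] if truth.module_of_gene[g] != "background" else GRAY
                 for g in m.gene_ids],
                index=m.gene_ids, dtype=object,
            )
        )
        part = network.module_eigengenes(m, part)
        n_mod = len(part.modules)
        edges = network.module_relationship_network(part, 0.0)
        assert len(edges) == n_mod * (n_mod - 1) // 2
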