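"""The five reconstruction methods: fixtures with analytic answers,
planted-structure recovery, and monotone-pruning invariants."""

import numpy as np
import pandas as pd
import pytest

from gcnbench.benchmark import edge_recovery
from gcnbench.errors import ConfigurationError
from gcnbench.reconstruct import (
    correlation_matrix,
    correlation_network,
    genenet_network,
    genenet_posteriors,
    network_from_scores,
    select_soft_power,
    space_network,
    space_pcor,
    wgcna_network,
)
from gcnbench.simulate import simulate_expression
from tests.conftest import planted_config


def toy_matrix(rows: dict[str, list[float]]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[f"s{i}" for i in range(len(next(iter(rows.values()))))])


class TestCorrelation:
    def test_perfect_linear_dependence(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        m = toy_matrix({"A": a, "B": [2 * v for v in a]})
        net = correlation_network(m, "pearson", r_threshold=1.0)
        assert net.has_edge("A", "B")
        assert net.edges[("A", "B")] == pytest.approx(1.0)

    def test_spearman_rank_invariance(self):
        a = list(np.linspace(0.0, 3.0, 10))
        m = toy_matrix({"A": a, "B": list(np.exp(a))})
        _, r_p = correlation_matrix(m, "pearson")
        _, r_s = correlation_matrix(m, "spearman")
        assert r_s[0, 1] == pytest.approx(1.0)
        assert r_p[0, 1] < 1.0

    def test_signed_mode_drops_negative_correlations(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        m = toy_matrix({"A": a, "B": [-v for v in a]})
        assert correlation_network(m, "pearson", 0.9, unsigned=True).n_e == 1
        assert correlation_network(m, "pearson", 0.9, unsigned=False).n_e == 0

    def test_zero_variance_gene_skipped_with_warning(self):
        m = toy_matrix({"A": [1.0, 2.0, 3.0, 4.0], "B": [2.0, 4.0, 6.0, 8.0],
                        "C": [5.0, 5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            net = correlation_network(m, "pearson", 0.5)
        assert "C" not in net.genes

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_edge_recovery(self, seed):
        matrix, _, truth = simulate_expression(planted_config(seed=seed))
        net = correlation_network(matrix, "pearson", r_threshold=0.6)
        assert edge_recovery(net, truth).f1 >= 0.7

    def test_monotone_pruning(self, planted_matrix):
        matrix, _, _ = planted_matrix
        edges = {}
        for thr in (0.5, 0.6, 0.7, 0.8, 0.9):
            edges[thr] = set(correlation_network(matrix, "pearson", thr).edges)
        for lo, hi in zip((0.5, 0.6, 0.7, 0.8), (0.6, 0.7, 0.8, 0.9)):
            assert edges[hi] <= edges[lo]

    def test_within_module_edges_more_likely_than_between(self):
        matrix, _, truth = simulate_expression(planted_config(seed=21, n_conditions=200))
        for thr in (0.3, 0.5, 0.7):
            net = correlation_network(matrix, "pearson", thr)
            n_within = sum(1 for e in net.edges if e in truth.true_edges)
            n_pairs_within = len(truth.true_edges)
            p = matrix.shape[0]
            n_pairs_between = p * (p - 1) // 2 - n_pairs_within
            p_within = n_within / n_pairs_within
            p_between = (net.n_e - n_within) / n_pairs_between
            assert p_within > p_between


class TestGeneNet:
    def test_full_shrinkage_gives_empty_network(self, chain3_sampler):
        net = genenet_network(chain3_sampler(0), omega=0.9, shrinkage=1.0)
        assert net.n_e == 0

    def test_chain_fixture_recovers_direct_edges(self, chain3_sampler):
        successes = 0
        for seed in range(5):
            _, _, post, _ = genenet_posteriors(chain3_sampler(seed))
            if post[0, 1] >= 0.9 and post[1, 2] >= 0.9 and post[0, 2] < 0.9:
                successes += 1
        assert successes >= 4

    def test_pcor_symmetric_and_lambda_in_unit_interval(self, chain3_sampler):
        _, pcor, _, info = genenet_posteriors(chain3_sampler(3))
        assert np.abs(pcor - pcor.T).max() < 1e-10
        assert 0.0 <= info["lambda_star"] <= 1.0

    def test_omega_on_pcor_thresholds_directly(self, chain3_sampler):
        net = genenet_network(chain3_sampler(1), omega=0.2, omega_on_pcor=True)
        assert net.has_edge("A", "B") and net.has_edge("B", "C")
        assert not net.has_edge("A", "C")


class TestSpace:
    def test_total_shrinkage_empties_network(self, chain3_sampler):
        net = space_network(chain3_sampler(0), rho_threshold=0.01, lambda_scale=50.0)
        assert net.n_e == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_chain_fixture_pcor_values(self, chain3_sampler, seed):
        _, rho = space_pcor(chain3_sampler(seed), lambda_scale=0.3)
        assert rho[0, 1] == pytest.approx(-0.4, abs=0.1)
        assert rho[1, 2] == pytest.approx(-0.4, abs=0.1)
        assert abs(rho[0, 2]) < 0.1

    def test_estimate_symmetric(self, chain3_sampler):
        _, rho = space_pcor(chain3_sampler(2), lambda_scale=0.3)
        assert np.abs(rho - rho.T).max() == 0.0

    def test_threshold_pruning_monotone(self, chain3_sampler):
        m = chain3_sampler(4)
        low = space_network(m, rho_threshold=0.05, lambda_scale=0.3)
        high = space_network(m, rho_threshold=0.3, lambda_scale=0.3)
        assert set(high.edges) <= set(low.edges)


class TestWgcna:
    def test_beta_one_matches_correlation_network(self, planted_matrix):
        matrix, _, _ = planted_matrix
        net_w, _ = wgcna_network(matrix, beta=1, tau=0.6)
        net_c = correlation_network(matrix, "pearson", r_threshold=0.6)
        assert set(net_w.edges) == set(net_c.edges)

    def test_tom_of_unweighted_triangle_is_one(self):
        # build data giving an exact triangle: three identical genes
        a = [1.0, 2.0, 3.0, 4.0, 1.5]
        m = toy_matrix({"A": a, "B": [v + 0.0 for v in a], "C": list(a)})
        m.loc["B"] += 1.0  # shift changes nothing for correlation
        _, tom = wgcna_network(m, beta=1, tau=0.5)
        offdiag = tom.to_numpy()[np.triu_indices(3, 1)]
        assert np.allclose(offdiag, 1.0)

    def test_invalid_beta_rejected(self, planted_matrix):
        matrix, _, _ = planted_matrix
        with pytest.raises(ConfigurationError):
            wgcna_network(matrix, beta=0, tau=0.5)

    def test_modules_survive_soft_thresholding(self):
        from gcnbench.benchmark import partition_similarity
        from gcnbench.community import walktrap_partition

        matrix, _, truth = simulate_expression(planted_config(seed=13))
        net, _ = wgcna_network(matrix, beta=5, tau=0.8**5)
        part = walktrap_partition(net)
        assert partition_similarity(part.module_of, truth.module_of) >= 0.8


class TestSelectSoftPower:
    def test_returns_lowest_qualifying_power(self):
        # heavy-tailed planted degrees: a scale-free-ish correlation structure
        from gcnbench.simulate import simulate_regulatory_network
        from gcnbench.benchmark import undirect_network

        # build expression whose correlation graph mirrors a scale-free net:
        # each gene = parent profile + noise along a preferential-attachment tree
        regnet = simulate_regulatory_network(120, 1, seed=0, hub_out_degree=40)
        rng = np.random.default_rng(0)
        profiles = {}
        order = []
        for reg, tgt in regnet.edges:
            if reg not in profiles:
                profiles[reg] = rng.standard_normal(80)
                order.append(reg)
            if tgt not in profiles:
                profiles[tgt] = 0.8 * profiles[reg] + 0.6 * rng.standard_normal(80)
                order.append(tgt)
        m = pd.DataFrame([profiles[g] for g in order], index=order)
        beta = select_soft_power(m, betas=list(range(1, 9)), r2_target=0.5)
        r2s = {}
        from gcnbench.reconstruct import wgcna_adjacency, _scale_free_r2
        for b in range(1, 9):
            _, a = wgcna_adjacency(m, b)
            r2s[b] = _scale_free_r2(a.sum(axis=1))
        qualifying = [b for b, r2 in r2s.items() if r2 is not None and r2 >= 0.5]
        assert beta == (min(qualifying) if qualifying else max(r2s, key=lambda b: r2s[b]))

    def test_pure_noise_falls_back_with_warning(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.standard_normal((40, 30)),
                         index=[f"g{i}" for i in range(40)])
        with pytest.warns(UserWarning, match="argmax"):
            select_soft_power(m, betas=list(range(1, 7)), r2_target=0.999)

    def test_betas_must_be_ascending(self, planted_matrix):
        matrix, _, _ = planted_matrix
        with pytest.raises(ConfigurationError):
            select_soft_power(matrix, betas=[5, 1])


class TestNetworkFromScores:
    def test_isolated_genes_dropped(self):
        scores = np.array([[0.0, 0.9, 0.1], [0.9, 0.0, 0.1], [0.1, 0.1, 0.0]])
        net = network_from_scores(["A", "B", "C"], scores, 0.5)
        assert net.genes == ["A", "B"]
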