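"""Gold-standard handling, edge addition, screening, ranking and
recovery metrics."""

import dataclasses
import math

import numpy as np
import pytest

from gcnbench.benchmark import (
    EdgeRecovery,
    MethodReport,
    ScreeningCriteria,
    add_random_edges,
    edge_recovery,
    ks_degree_distance,
    partition_similarity,
    project_gene_sets,
    rank_methods,
    screen_candidates,
    undirect_network,
)
from gcnbench.community import Partition
from gcnbench.enrichment import EnrichmentSummary
from gcnbench.errors import ConfigurationError
from gcnbench.network import DirectedRegNet, Network
from gcnbench.simulate import GroundTruth, simulate_regulatory_network
from gcnbench.topology import DegreeDistribution, PowerLawFit, degree_distribution


class TestUndirect:
    def test_reciprocal_pair_collapses(self):
        net = undirect_network(DirectedRegNet(edges=[("A", "B"), ("B", "A")]))
        assert net.n_e == 1 and net.has_edge("A", "B")

    def test_star_regulator_degree(self):
        edges = [("tf", f"g{i}") for i in range(100)]
        net = undirect_network(DirectedRegNet(edges=edges))
        assert net.degree()["tf"] == 100

    def test_collapse_never_adds_edges(self):
        regnet = simulate_regulatory_network(100, 2, seed=0, hub_out_degree=20)
        assert undirect_network(regnet).n_e <= len(regnet.edges)

    def test_idempotent_through_round_trip(self, tmp_path):
        from gcnbench import io as gio

        regnet = simulate_regulatory_network(50, 1, seed=1, hub_out_degree=10)
        net = undirect_network(regnet)
        path = tmp_path / "net.tsv"
        gio.write_network(net, str(path))
        again = gio.read_network(str(path))
        assert set(again.edges) == set(net.edges)


class TestAddRandomEdges:
    def test_phi_zero_is_identity(self, two_triangle_bridge):
        out = add_random_edges(two_triangle_bridge, 0.0, seed=1)
        assert out.edges == two_triangle_bridge.edges

    @pytest.mark.parametrize("phi", [0.1, 0.5, 1.0])
    def test_exact_added_count_and_superset(self, phi):
        net = undirect_network(simulate_regulatory_network(200, 2, seed=3, hub_out_degree=40))
        out = add_random_edges(net, phi, seed=9)
        assert out.n_e == net.n_e + math.ceil(phi * net.n_e)
        assert set(net.edges) <= set(out.edges)

    def test_deterministic_under_seed(self):
        net = undirect_network(simulate_regulatory_network(100, 1, seed=2, hub_out_degree=20))
        a = add_random_edges(net, 0.5, seed=4)
        b = add_random_edges(net, 0.5, seed=4)
        assert a.edges == b.edges

    @pytest.mark.parametrize("seed", range(10))
    def test_degree_cdf_shifts_right(self, seed):
        """Augmentation moves the degree CDF rightward (at or below the
        original at every k), i.e. stochastic dominance."""
        net = undirect_network(simulate_regulatory_network(500, 2, seed=seed, hub_out_degree=60))
        aug = add_random_edges(net, 0.5, seed=seed)
        d0, d1 = degree_distribution(net), degree_distribution(aug)
        support = sorted(set(d0.pk) | set(d1.pk))
        f0 = np.cumsum([d0.pk.get(k, 0.0) for k in support])
        f1 = np.cumsum([d1.pk.get(k, 0.0) for k in support])
        assert np.all(f1 <= f0 + 1e-12)

    def test_insufficient_capacity_is_error(self):
        net = Network()
        for a, b in [("a", "b"), ("b", "c"), ("a", "c")]:
            net.add_edge(a, b)
        with pytest.raises(ValueError, match="non-adjacent"):
            add_random_edges(net, 1.0, seed=0)


class TestKsDistance:
    def test_identical_distributions(self):
        d = DegreeDistribution.from_degrees([1, 2, 2, 3])
        assert ks_degree_distance(d, d) == 0.0

    def test_disjoint_supports(self):
        a = DegreeDistribution.from_degrees([1, 1])
        b = DegreeDistribution.from_degrees([10, 10])
        assert ks_degree_distance(a, b) == 1.0

    def test_symmetry(self):
        a = DegreeDistribution.from_degrees([1, 2, 3, 4])
        b = DegreeDistribution.from_degrees([2, 2, 5])
        assert ks_degree_distance(a, b) == ks_degree_distance(b, a)


def make_candidate(n_nodes: int, n_edges: int, q: float, seed: int = 0):
    rng = np.random.default_rng(seed)
    net = Network()
    nodes = [f"g{i}" for i in range(n_nodes)]
    for a, b in zip(nodes, nodes[1:]):
        net.add_edge(a, b)
    while net.n_e < n_edges:
        i, j = rng.integers(0, n_nodes, 2)
        if i != j and not net.has_edge(nodes[i], nodes[j]):
            net.add_edge(nodes[i], nodes[j])
    part = Partition(module_of={g: 0 for g in nodes}, modules=[nodes], q=q,
                     method="fixture")
    return net, part


class TestScreening:
    def test_sparse_candidate_discarded(self):
        crit = ScreeningCriteria(q_min=0.5, g_min=500, ratio_max=10)
        cand = make_candidate(300, 400, q=0.8)
        kept, discarded = screen_candidates([cand], crit)
        assert not kept
        assert discarded[0][2] == "very sparse connectivity"

    def test_low_modularity_and_high_connectivity_reasons(self):
        crit = ScreeningCriteria(q_min=0.5, g_min=50, ratio_max=3)
        dense = make_candidate(60, 250, q=0.9, seed=1)  # ratio > 3
        weak = make_candidate(60, 100, q=0.2, seed=2)
        kept, discarded = screen_candidates([dense, weak], crit)
        reasons = {r for _, _, r in discarded}
        assert reasons == {"very high connectivity", "low modularity"}

    def test_all_pass_is_permutation_of_input(self):
        crit = ScreeningCriteria(q_min=0.1, g_min=10, ratio_max=10)
        cands = [make_candidate(60, 100, q=0.7, seed=s) for s in range(3)]
        kept, discarded = screen_candidates(cands, crit)
        assert not discarded and len(kept) == 3
        assert {id(c[0]) for c in kept} == {id(c[0]) for c in cands}

    def test_midrange_ratio_passes_default_cap(self):
        # an edges-to-genes ratio around 6.5 clears ratio_max = 10
        crit = ScreeningCriteria(q_min=0.1, g_min=50, ratio_max=10)
        cand = make_candidate(100, 650, q=0.6, seed=3)
        kept, _ = screen_candidates([cand], crit)
        assert kept and kept[0][0].n_e / kept[0][0].n_g == pytest.approx(6.5)

    def test_survivors_ordered_by_gold_ratio_proximity(self):
        crit = ScreeningCriteria(q_min=0.1, g_min=10, ratio_max=20, gold_ratios=[2.0])
        far = make_candidate(50, 500, q=0.7, seed=4)    # ratio 10
        near = make_candidate(50, 110, q=0.7, seed=5)   # ratio 2.2
        kept, _ = screen_candidates([far, near], crit)
        assert kept[0][0] is near[0]

    def test_empty_candidates_is_error(self):
        with pytest.raises(ConfigurationError):
            screen_candidates([], ScreeningCriteria())

    def test_union_of_kept_and_discarded_is_input(self):
        crit = ScreeningCriteria(q_min=0.5, g_min=55, ratio_max=3)
        cands = [make_candidate(60, 100, q=q, seed=s)
                 for s, q in enumerate([0.8, 0.2, 0.6])]
        kept, discarded = screen_candidates(cands, crit)
        assert len(kept) + len(discarded) == 3


def report(method: str, sig: int, psi1: float, psi2: float, q: float, r2: float) -> MethodReport:
    return MethodReport(
        method=method,
        powerlaw=PowerLawFit(gamma=2.0, k_min=1, r2_loglog=r2, ks_stat=0.1, method="mle"),
        enrichment=EnrichmentSummary(psi1=psi1, psi2=psi2, psi2_literal=psi2,
                                     total_significant_terms=sig,
                                     n_enriched_modules=1, n_annotated_modules=1,
                                     alpha=0.05),
        q=q,
    )


class TestRankMethods:
    def test_dominant_method_ranks_first(self):
        a = report("alpha", 10, 2.0, 2.0, 0.8, 0.9)
        b = report("beta", 2, 1.0, 0.5, 0.4, 0.5)
        ranked = rank_methods([a, b])
        assert [r.method for r in ranked] == ["alpha", "beta"]
        assert ranked[0].overall_rank == 1

    def test_permutation_invariance(self):
        reps = [report(m, s, p1, p2, q, r2) for m, s, p1, p2, q, r2 in [
            ("a", 5, 1.2, 1.0, 0.7, 0.8), ("b", 8, 2.0, 1.5, 0.5, 0.6),
            ("c", 1, 1.0, 0.2, 0.9, 0.9)]]
        fwd = {r.method: r.overall_rank for r in rank_methods([dataclasses.replace(r) for r in reps])}
        rev = {r.method: r.overall_rank for r in rank_methods([dataclasses.replace(r) for r in reversed(reps)])}
        assert fwd == rev

    def test_missing_summary_is_error(self):
        a = report("a", 1, 1, 1, 0.5, 0.5)
        b = report("b", 1, 1, 1, 0.5, 0.5)
        b.enrichment = None
        with pytest.raises(ConfigurationError, match="enrichment"):
            rank_methods([a, b])

    def test_single_report_is_error(self):
        with pytest.raises(ConfigurationError):
            rank_methods([report("a", 1, 1, 1, 0.5, 0.5)])


def truth_from_edges(edges, genes) -> GroundTruth:
    return GroundTruth(module_of={g: "M0" for g in genes},
                       true_edges=set(edges), regulators=[])


class TestEdgeRecovery:
    def test_exact_prediction(self):
        edges = [("a", "b"), ("b", "c")]
        net = Network.from_edges([(a, b, 1.0) for a, b in edges])
        truth = truth_from_edges(edges, "abc")
        r = edge_recovery(net, truth)
        assert (r.precision, r.recall, r.f1) == (1.0, 1.0, 1.0)

    def test_empty_prediction_flagged(self):
        truth = truth_from_edges([("a", "b")], "ab")
        r = edge_recovery(Network(), truth)
        assert r == EdgeRecovery(0.0, 0.0, 0.0, empty_prediction=True)

    def test_half_false_edges(self):
        true_edges = [("a", "b"), ("b", "c")]
        pred = Network.from_edges([("a", "b", 1), ("b", "c", 1),
                                   ("a", "d", 1), ("c", "d", 1)])
        truth = truth_from_edges(true_edges, "abcd")
        r = edge_recovery(pred, truth)
        assert r.precision == 0.5 and r.recall == 1.0
        assert r.f1 == pytest.approx(2 / 3)


class TestPartitionSimilarity:
    def test_identical_partitions(self):
        a = {"a": 0, "b": 0, "c": 1}
        assert partition_similarity(a, dict(a)) == pytest.approx(1.0)

    def test_symmetric(self):
        a = {"a": 0, "b": 0, "c": 1, "d": 1}
        b = {"a": 0, "b": 1, "c": 1, "d": 1}
        assert partition_similarity(a, b) == partition_similarity(b, a)

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(100)]
        truth = {g: i % 4 for i, g in enumerate(genes)}
        aris = []
        for _ in range(100):
            labels = rng.permutation([i % 4 for i in range(100)])
            aris.append(partition_similarity(truth, dict(zip(genes, labels))))
        assert abs(np.mean(aris)) <= 0.05

    def test_disjoint_gene_sets_error(self):
        with pytest.raises(ValueError):
            partition_similarity({"a": 0}, {"b": 0})


class TestProjectGeneSets:
    @pytest.fixture
    def setting(self, two_triangle_bridge):
        part = Partition(module_of={g: (0 if g in "abc" else 1)
                                   for g in two_triangle_bridge.genes},
                         modules=[["a", "b", "c"], ["d", "e", "f"]],
                         q=5 / 14, method="fixture")
        return two_triangle_bridge, part

    def test_set_inside_one_module_cohesion_one(self, setting):
        net, part = setting
        rows = project_gene_sets(part, net, {"regA": {"a", "b", "c"}})
        assert rows[0]["cohesion"] == 1.0 and rows[0]["coverage"] == 1.0

    def test_absent_set_coverage_zero(self, setting):
        net, part = setting
        rows = project_gene_sets(part, net, {"regX": {"z1", "z2"}})
        assert rows[0]["coverage"] == 0.0
        assert math.isnan(rows[0]["cohesion"])

    def test_dilution_strictly_lowers_cohesion(self, setting):
        net, part = setting
        pure = project_gene_sets(part, net, {"r": {"a", "b", "c"}})[0]["cohesion"]
        diluted = project_gene_sets(part, net, {"r": {"a", "b", "c", "d", "e"}})[0]["cohesion"]
        assert diluted < pure

    def test_empty_set_rejected(self, setting):
        net, part = setting
        with pytest.raises(ConfigurationError):
            project_gene_sets(part, net, {"r": set()})
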