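import numpy as np
import pandas as pd
import pytest

from microassembly import networks as net_mod
from microassembly import synthetic
from microassembly.tables import AssociationNetwork, DataError


@pytest.fixture(scope="module")
def sim_nets():
    nets, truth = synthetic.simulate_networks(
        ["A", "B", "C"], nodes_per_location=80, edges_per_location=120,
        n_planted_shared=5, seed=17,
    )
    return nets, truth


def _toy_network():
    domains = {"b1": "bacteria", "b2": "bacteria", "b3": "bacteria",
               "f1": "fungi", "f2": "fungi"}
    edges = [("b1", "f1"), ("b2", "f1"), ("b1", "b2"), ("b3", "f2")]
    return AssociationNetwork.from_edges(edges, domains)


class TestExtractBfEdges:
    def test_within_domain_edges_dropped(self):
        bf = net_mod.extract_bf_edges(_toy_network())
        assert bf.edge_set() == {
            frozenset(("b1", "f1")), frozenset(("b2", "f1")),
            frozenset(("b3", "f2")),
        }

    def test_isolated_nodes_kept_and_flagged(self):
        domains = {"b1": "bacteria", "b2": "bacteria", "f1": "fungi"}
        net = AssociationNetwork.from_edges([("b1", "b2")], domains,
                                            nodes=["b1", "b2", "f1"])
        bf = net_mod.extract_bf_edges(net)
        assert set(bf.graph.nodes) == {"b1", "b2", "f1"}
        assert all(bf.graph.nodes[v]["isolated"] for v in bf.graph.nodes)


class TestNetworkStats:
    def test_toy_counts(self):
        stats = net_mod.network_stats(_toy_network(), modules=False)
        assert (stats.n_nodes, stats.n_bacteria, stats.n_fungi) == (5, 3, 2)
        assert stats.n_edges == 4
        assert stats.linkage_density == pytest.approx(2 * 4 / 5)
        assert stats.edge_density == pytest.approx(100 * 4 / 10)
        assert stats.max_degree == 2

    def test_published_style_arithmetic(self):
        # a network of 1527 bacteria, 423 fungi and 10651 edges has linkage
        # density 10.9 and edge density 0.56%
        stats = net_mod.summary_from_counts(1527, 423, 10651)
        assert stats.n_nodes == 1950
        assert round(stats.linkage_density, 1) == 10.9
        assert round(stats.edge_density, 2) == 0.56

    def test_complete_graph_density_100(self):
        domains = {"b1": "bacteria", "b2": "bacteria", "f1": "fungi"}
        net = AssociationNetwork.from_edges(
            [("b1", "b2"), ("b1", "f1"), ("b2", "f1")], domains
        )
        stats = net_mod.network_stats(net, modules=False)
        assert stats.edge_density == pytest.approx(100.0)

    def test_empty_network_rejected(self):
        import networkx as nx

        with pytest.raises(DataError, match="empty"):
            net_mod.network_stats(AssociationNetwork(nx.Graph()))


class TestModules:
    def test_two_cliques_found(self):
        domains = {f"b{i}": "bacteria" for i in range(6)}
        clique1 = [("b0", "b1"), ("b0", "b2"), ("b1", "b2")]
        clique2 = [("b3", "b4"), ("b3", "b5"), ("b4", "b5")]
        net = AssociationNetwork.from_edges(clique1 + clique2, domains)
        partition, q = net_mod.detect_modules(net)
        assert sorted(map(sorted, partition)) == [
            ["b0", "b1", "b2"], ["b3", "b4", "b5"]
        ]
        assert q > 0.3

    def test_partition_covers_all_nodes(self, sim_nets):
        nets, _ = sim_nets
        net = nets["A"]
        partition, _ = net_mod.detect_modules(net)
        covered = set().union(*partition)
        assert covered == set(net.graph.nodes)
        assert sum(len(m) for m in partition) == net.graph.number_of_nodes()

    def test_edgeless_network_gives_singletons(self):
        domains = {"b1": "bacteria", "f1": "fungi"}
        net = AssociationNetwork.from_edges([], domains, nodes=["b1", "f1"])
        partition, q = net_mod.detect_modules(net)
        assert sorted(map(sorted, partition)) == [["b1"], ["f1"]]
        assert q == 0.0

    def test_compare_identical_partitions_score_one(self):
        p = [{"a", "b"}, {"c", "d", "e"}]
        out = net_mod.compare_modules(p, [set(m) for m in p])
        assert out["score"] == pytest.approx(1.0)

    def test_compare_disjoint_node_sets(self):
        out = net_mod.compare_modules([{"a"}], [{"z"}])
        assert out["no_shared_nodes"]
        assert out["score"] == 0.0


class TestNullModels:
    def test_rewire_preserves_every_degree(self, sim_nets):
        nets, _ = sim_nets
        g = nets["A"].graph
        before = dict(g.degree())
        for null in net_mod.random_networks(nets["A"], 5, "rewire", seed=1):
            assert dict(null.graph.degree()) == before

    def test_er_preserves_nodes_and_edge_count(self, sim_nets):
        nets, _ = sim_nets
        g = nets["A"].graph
        for null in net_mod.random_networks(nets["A"], 5, "er", seed=1):
            assert set(null.graph.nodes) == set(g.nodes)
            assert null.graph.number_of_edges() == g.number_of_edges()

    def test_er_randomizes_edges(self, sim_nets):
        nets, _ = sim_nets
        null = next(iter(net_mod.random_networks(nets["A"], 1, "er", seed=2)))
        assert null.edge_set() != nets["A"].edge_set()

    def test_seeded_reproducibility(self, sim_nets):
        nets, _ = sim_nets
        for model in ("rewire", "er"):
            a = [n.edge_set() for n in net_mod.random_networks(nets["A"], 3, model, seed=5)]
            b = [n.edge_set() for n in net_mod.random_networks(nets["A"], 3, model, seed=5)]
            assert a == b

    def test_unknown_null_model_rejected(self, sim_nets):
        nets, _ = sim_nets
        with pytest.raises(DataError, match="unknown null model"):
            list(net_mod.random_networks(nets["A"], 1, "bogus"))

    def test_typed_er_preserves_association_type_counts(self, sim_nets):
        nets, _ = sim_nets
        net = nets["B"]
        domains = net.domains()
        rng = np.random.default_rng(0)
        null = net_mod._typed_er_edge_set(net, rng)
        assert len(null) == net.graph.number_of_edges()
        # source networks are purely bacterial-fungal: so must be the null
        for pair in null:
            u, v = tuple(pair)
            assert {domains[u], domains[v]} == {"bacteria", "fungi"}


class TestSharedAssociations:
    def test_hand_intersection(self):
        domains = {"b1": "bacteria", "f1": "fungi", "f2": "fungi"}
        n1 = AssociationNetwork.from_edges([("b1", "f1"), ("b1", "f2")], domains)
        n2 = AssociationNetwork.from_edges([("b1", "f1")], domains)
        shared = net_mod.shared_associations({"x": n1, "y": n2})
        assert shared == {frozenset(("b1", "f1"))}

    def test_planted_edges_recovered(self, sim_nets):
        nets, truth = sim_nets
        shared = net_mod.shared_associations(nets)
        planted = {frozenset(p) for p in truth["planted_pairs"]}
        assert planted <= shared

    def test_single_network_rejected(self, sim_nets):
        nets, _ = sim_nets
        with pytest.raises(DataError, match="two networks"):
            net_mod.shared_associations(nets, subset=["A"])


class TestSharedEdgeTest:
    def test_planted_sharing_detected(self, sim_nets):
        nets, _ = sim_nets
        out = net_mod.shared_edge_test(nets, n=199, null_model="er", seed=3)
        assert out.p_empirical <= 0.05
        assert out.observed_shared >= 5

    def test_p_value_floor_is_attained(self, sim_nets):
        nets, _ = sim_nets
        out = net_mod.shared_edge_test(nets, n=199, null_model="er", seed=3)
        assert out.p_empirical >= 1.0 / 200.0

    def test_rewire_null_also_detects_planting(self, sim_nets):
        nets, _ = sim_nets
        out = net_mod.shared_edge_test(nets, n=99, null_model="rewire", seed=3)
        assert out.p_empirical <= 0.05

    def test_null_counts_length_and_p_formula(self, sim_nets):
        nets, _ = sim_nets
        out = net_mod.shared_edge_test(nets, n=99, null_model="er", seed=9)
        assert out.null_counts.shape == (99,)
        expected = (1 + int((out.null_counts >= out.observed_shared).sum())) / 100
        assert out.p_empirical == pytest.approx(expected)

    def test_reproducible_for_seed(self, sim_nets):
        nets, _ = sim_nets
        a = net_mod.shared_edge_test(nets, n=49, seed=11)
        b = net_mod.shared_edge_test(nets, n=49, seed=11)
        assert a.p_empirical == b.p_empirical
        assert (a.null_counts == b.null_counts).all()


class TestAttachNcmClasses:
    def _results_stub(self, classes: dict):
        class _Stub:
            per_otu = pd.DataFrame({"otu_class": pd.Series(classes)})
        return _Stub()

    def test_node_classes_and_unassigned(self):
        net = _toy_network()
        res = self._results_stub({"b1": "above", "b2": "neutral", "f1": "below"})
        out = net_mod.attach_ncm_classes(net, res)
        assert out["node_class"]["b1"] == "above"
        assert out["node_class"]["b3"] == "unassigned"

    def test_contingency_sums_to_edge_count(self):
        net = _toy_network()
        res = self._results_stub(
            {"b1": "above", "b2": "neutral", "b3": "neutral",
             "f1": "below", "f2": "neutral"}
        )
        out = net_mod.attach_ncm_classes(net, res)
        assert out["contingency"].to_numpy().sum() == net.graph.number_of_edges()
        assert sum(out["edge_class_pairs"].values()) == net.graph.number_of_edges()

    def test_percentages_sum_to_100_per_domain(self):
        net = _toy_network()
        res = self._results_stub({"b1": "above", "f1": "below"})
        out = net_mod.attach_ncm_classes(net, res)
        for dom, pcts in out["class_percent_by_domain"].items():
            assert sum(pcts.values()) == pytest.approx(100.0)


class TestNaiveInference:
    def test_perfectly_correlated_pair_linked(self, rng):
        from microassembly.tables import OtuTable

        # a perfectly proportional pair among many independent taxa; with
        # few taxa the CLR closure would itself induce spurious correlation
        n_indep, n_samp = 15, 30
        base = rng.integers(20, 200, size=n_samp)
        indep = rng.integers(20, 200, size=(n_indep, n_samp))
        counts = pd.DataFrame(
            np.vstack([base, 2 * base, indep]),
            index=["b1", "b2"] + [f"x{i}" for i in range(n_indep)],
            columns=[f"s{j}" for j in range(n_samp)],
        )
        domain = pd.Series(
            ["bacteria", "bacteria"] + ["fungi"] * n_indep, index=counts.index
        )
        table = OtuTable(counts, domain)
        net = net_mod.naive_network_inference(table, threshold=0.9)
        assert frozenset(("b1", "b2")) in net.edge_set()
        assert not any("x" in "".join(sorted(e)) for e in net.edge_set())

    def test_requires_enough_samples(self, small_table):
        with pytest.raises(DataError, match="20 samples"):
            net_mod.naive_network_inference(small_table)


class TestSimulateNetworks:
    def test_truth_and_bipartite_structure(self, sim_nets):
        nets, truth = sim_nets
        assert len(truth["planted_pairs"]) == 5
        for net in nets.values():
            domains = net.domains()
            assert net.graph.number_of_edges() == 120
            for u, v in net.graph.edges():
                assert {domains[u], domains[v]} == {"bacteria", "fungi"}

    def test_too_many_planted_rejected(self):
        with pytest.raises(DataError, match="plant"):
            synthetic.simulate_networks(["A"], 20, 5, n_planted_shared=6)
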