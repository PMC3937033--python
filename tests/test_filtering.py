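import networkx as nx
import numpy as np
import pandas as pd
import pytest

from conftest import random_weighted_graph
from oracles import anchors_connected_bfs, naive_topology
from tppin.filtering import (
    AnchorConfigurationError,
    AnchorConstraint,
    anchors_connected,
    filter_network,
    topology_record,
)
from tppin.geneset import GeneSet
from tppin.network_io import canonical_pair


def significance_table(graph: nx.Graph, pvals: dict) -> pd.DataFrame:
    rows = []
    for u, v in graph.edges():
        a, b = canonical_pair(u, v)
        rows.append((a, b, graph[u][v].get("weight", 1.0), pvals[(a, b)]))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight", "p_value"])


@pytest.fixture
def worked_example():
    """Nodes A-D; links AB(0.9), CD(0.7), BC(0.5), AC(0.3); anchors A vs D."""
    g = nx.Graph()
    for a, b in [("A", "B"), ("C", "D"), ("B", "C"), ("A", "C")]:
        g.add_edge(a, b, weight=1.0)
    pvals = {("A", "B"): 0.9, ("C", "D"): 0.7, ("B", "C"): 0.5, ("A", "C"): 0.3}
    sig = significance_table(g, pvals)
    constraint = AnchorConstraint(GeneSet("a", {"A"}), GeneSet("b", {"D"}))
    return g, sig, constraint


class TestAnchorsConnected:
    def test_path_and_split(self):
        g = nx.path_graph(["A", "B", "C"])
        c = AnchorConstraint(GeneSet("a", {"A"}), GeneSet("b", {"C"}))
        assert anchors_connected(g, c)
        g2 = nx.Graph()
        g2.add_edge("A", "B")
        g2.add_node("C")
        assert not anchors_connected(g2, c)

    def test_missing_anchor_is_configuration_error(self):
        g = nx.path_graph(["A", "B"])
        c = AnchorConstraint(GeneSet("a", {"A"}), GeneSet("b", {"Z"}))
        with pytest.raises(AnchorConfigurationError):
            anchors_connected(g, c)

    def test_matches_bfs_oracle_on_random_graphs(self):
        rng = np.random.default_rng(41)
        for _ in range(30):
            g = random_weighted_graph(rng, 100, int(rng.integers(50, 150)))
            nodes = sorted(g.nodes())
            set_a = set(rng.choice(nodes, size=3, replace=False))
            set_b = set(rng.choice(nodes, size=3, replace=False))
            c = AnchorConstraint(GeneSet("a", set_a), GeneSet("b", set_b))
            assert anchors_connected(g, c) == anchors_connected_bfs(g, set_a, set_b)


class TestTopologyRecord:
    def test_connected_path(self):
        g = nx.path_graph(4)
        rec = topology_record(g)
        assert (rec.diameter, rec.giant_relative_size,
                rec.mean_isolated_component_size) == (3.0, 1.0, 0.0)

    def test_path_plus_dyad(self):
        g = nx.path_graph(4)
        g.add_edge("x", "y")
        rec = topology_record(g)
        assert rec.diameter == 3.0
        assert rec.giant_relative_size == pytest.approx(4 / 6)
        assert rec.mean_isolated_component_size == 2.0

    def test_star(self):
        rec = topology_record(nx.star_graph(4))
        assert rec.diameter == 2.0

    def test_empty_network(self):
        rec = topology_record(nx.Graph())
        assert rec == topology_record(nx.Graph())
        assert rec.diameter == rec.giant_relative_size == 0.0

    def test_matches_component_oracle_on_random_graphs(self):
        rng = np.random.default_rng(43)
        for _ in range(30):
            n = int(rng.integers(2, 50))
            g = random_weighted_graph(rng, n, int(rng.integers(1, max(2, n))))
            rec = topology_record(g)
            diameter, n_rel, mean_s = naive_topology(g, g)
            assert rec.diameter == pytest.approx(diameter)
            assert rec.giant_relative_size == pytest.approx(n_rel)
            assert rec.mean_isolated_component_size == pytest.approx(mean_s)


class TestFilterNetwork:
    def test_worked_example_trace_and_stop(self, worked_example):
        g, sig, constraint = worked_example
        res = filter_network(g, sig, [constraint])
        accepted = res.trace[res.trace.accepted]
        assert [(r.gene_a, r.gene_b) for r in accepted.itertuples()] == [("A", "B")]
        assert res.stop_link == ("C", "D")
        assert res.stop_reason == "anchor disconnection"
        assert {canonical_pair(u, v) for u, v in res.network.edges()} == \
            {("B", "C"), ("C", "D"), ("A", "C")}

    def test_immediate_stop_when_bridge_has_largest_p(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=1.0)
        g.add_edge("B", "C", weight=1.0)
        sig = significance_table(g, {("A", "B"): 0.9, ("B", "C"): 0.2})
        c = AnchorConstraint(GeneSet("a", {"A"}), GeneSet("b", {"C"}))
        res = filter_network(g, sig, [c])
        assert res.trace.accepted.sum() == 0
        assert res.stop_link == ("A", "B")
        assert res.network.number_of_edges() == 2

    def test_initially_violated_constraint_rejected(self):
        g = nx.Graph()
        g.add_edge("A", "B")
        g.add_node("C")
        sig = significance_table(g, {("A", "B"): 0.5})
        c = AnchorConstraint(GeneSet("a", {"A"}), GeneSet("b", {"C"}))
        with pytest.raises(AnchorConfigurationError):
            filter_network(g, sig, [c])

    def test_missing_pvalue_rejected(self, worked_example):
        g, sig, constraint = worked_example
        with pytest.raises(ValueError, match="lack a p-value"):
            filter_network(g, sig.iloc[:2], [constraint])

    def test_random_networks_contract(self):
        """Trace p non-increasing, anchors connected at every accepted step,
        survivors a subset of the input, stop link restored."""
        rng = np.random.default_rng(47)
        checked = 0
        while checked < 25:
            g = random_weighted_graph(rng, 30, 60)
            nodes = sorted(g.nodes())
            set_a = {nodes[int(rng.integers(len(nodes)))]}
            set_b = {nodes[int(rng.integers(len(nodes)))]}
            if set_a == set_b or not anchors_connected_bfs(g, set_a, set_b):
                continue
            checked += 1
            pvals = {canonical_pair(u, v): float(rng.random())
                     for u, v in g.edges()}
            sig = significance_table(g, pvals)
            c = AnchorConstraint(GeneSet("a", set_a), GeneSet("b", set_b))
            res = filter_network(g, sig, [c])

            accepted = res.trace[res.trace.accepted]
            ps = accepted.p_value.to_numpy()
            assert (np.diff(ps) <= 1e-12).all()
            # replay: anchors stay connected after every accepted removal
            replay = g.copy()
            for row in accepted.itertuples(index=False):
                replay.remove_edge(row.gene_a, row.gene_b)
                assert anchors_connected_bfs(replay, set_a, set_b)
            surviving = {canonical_pair(u, v) for u, v in res.network.edges()}
            assert surviving <= {canonical_pair(u, v) for u, v in g.edges()}
            if res.stop_link is not None:
                assert res.stop_link in surviving
            # giant component shrinks monotonically
            giant = res.topology.giant_relative_size.to_numpy()
            assert (np.diff(giant) <= 1e-12).all()

    def test_topology_series_matches_replayed_records(self, worked_example):
        g, sig, constraint = worked_example
        res = filter_network(g, sig, [constraint])
        replay = g.copy()
        accepted = res.trace[res.trace.accepted]
        for step, row in enumerate(accepted.itertuples(index=False)):
            replay.remove_edge(row.gene_a, row.gene_b)
            rec = topology_record(replay, g)
            series = res.topology.iloc[step]
            assert series.diameter == pytest.approx(rec.diameter)
            assert series.giant_relative_size == pytest.approx(
                rec.giant_relative_size)
            assert series.mean_isolated_component_size == pytest.approx(
                rec.mean_isolated_component_size)
            assert series.links_removed_fraction == pytest.approx(
                rec.links_removed_fraction)

    def test_refiltering_output_is_safe(self, worked_example):
        g, sig, constraint = worked_example
        res = filter_network(g, sig, [constraint])
        surviving = {canonical_pair(u, v) for u, v in res.network.edges()}
        keep = sig.apply(lambda r: (r.gene_a, r.gene_b) in surviving, axis=1)
        res2 = filter_network(res.network, sig[keep], [constraint])
        assert anchors_connected(res2.network, constraint)
        assert {canonical_pair(u, v) for u, v in res2.network.edges()} <= surviving

    def test_sequential_mode_enforces_all_constraints(self):
        rng = np.random.default_rng(53)
        g = random_weighted_graph(rng, 40, 90)
        nodes = sorted(g.nodes())
        sets = [GeneSet(n, {nodes[i]}) for n, i in
                [("a", 0), ("b", 15), ("c", 30)]]
        cons = [AnchorConstraint(sets[0], sets[1]),
                AnchorConstraint(sets[0], sets[2])]
        for c in cons:
            if not anchors_connected(g, c):
                pytest.skip("random graph disconnected for this seed")
        pvals = {canonical_pair(u, v): float(rng.random()) for u, v in g.edges()}
        sig = significance_table(g, pvals)
        res = filter_network(g, sig, cons, mode="sequential")
        for c in cons:
            assert anchors_connected(res.network, c)
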