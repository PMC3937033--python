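import networkx as nx
import numpy as np
import pytest

from tppin.correlation import filter_expressed_genes, weigh_network
from tppin.filtering import AnchorConstraint, filter_network
from tppin.gloss import empirical_distribution, gloss_pvalues
from tppin.synthetic import (
    anchor_sets,
    default_scenario,
    generate_expression,
    generate_network,
    planted_scenario,
)

# the one fixed seed used by every scenario-level statistical check
FIXED_SEED = 0


@pytest.fixture
def four_cycle() -> nx.Graph:
    """Cycle A-B-C-D-A with weights (1, 1, 1, 2)."""
    g = nx.Graph()
    g.add_edge("A", "B", weight=1.0)
    g.add_edge("B", "C", weight=1.0)
    g.add_edge("C", "D", weight=1.0)
    g.add_edge("D", "A", weight=2.0)
    return g


class PipelineRun:
    """End-to-end run of the core pipeline on one synthetic scenario."""

    def __init__(self, scenario):
        self.scenario = scenario
        self.raw_network = generate_network(scenario)
        expr = generate_expression(scenario, self.raw_network)
        self.expression = filter_expressed_genes(expr)
        self.weighted = weigh_network(self.raw_network, self.expression).network
        self.distribution = empirical_distribution(self.weighted, 1.0)
        self.significance = gloss_pvalues(self.weighted, self.distribution)
        anchors = anchor_sets(self.raw_network)
        self.constraints = [
            AnchorConstraint(anchors["tcr_complex"], anchors["nfkb"]),
            AnchorConstraint(anchors["tcr_complex"], anchors["nfat"]),
        ]
        self.result = filter_network(self.weighted, self.significance,
                                     self.constraints)


@pytest.fixture(scope="session")
def default_run() -> PipelineRun:
    return PipelineRun(default_scenario(FIXED_SEED))


@pytest.fixture(scope="session")
def planted_run() -> PipelineRun:
    return PipelineRun(planted_scenario(FIXED_SEED))


def random_weighted_graph(rng: np.random.Generator, n_nodes: int, n_edges: int,
                          weights=None) -> nx.Graph:
    """Random simple graph with the requested edge count and random weights."""
    g = nx.gnm_random_graph(n_nodes, n_edges, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes()})
    for u, v in g.edges():
        if weights is None:
            g[u][v]["weight"] = float(rng.integers(1, 5))
        else:
            g[u][v]["weight"] = float(rng.choice(weights))
    return g
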