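"""Link-weight-randomization (LWRN) sensitivity analysis.

A fraction of links is chosen uniformly at random and their weights are
randomized among themselves (a permutation, so the global weight multiset
— which the significance null model depends on — is conserved exactly;
resampling with replacement is available behind a flag).  The whole
significance + filtering pipeline is re-run on each randomized copy and
six statistics of the filtered network are compared with the reference
filtered network: mean node degree, mean path length over connected node
pairs, mean node betweenness, mean link betweenness, mean local
clustering coefficient, and the link intersection with the reference
(count and fraction).  Shortest-path statistics are unweighted (hop
count): weights are similarity scores, not distances.
"""

from __future__ import annotations

import logging
from typing import Callable

import networkx as nx
import numpy as np
import pandas as pd

from tppin.filtering import AnchorConstraint, FilterResult, filter_network
from tppin.gloss import empirical_distribution, gloss_pvalues
from tppin.network_io import canonical_pair

logger = logging.getLogger(__name__)

STATISTIC_COLUMNS = [
    "mean_degree", "mean_path_length", "mean_node_betweenness",
    "mean_link_betweenness", "mean_clustering",
    "intersection_count", "intersection_fraction",
]


def randomize_weights(
    network: nx.Graph,
    fraction: float,
    seed: int | np.random.Generator | None = None,
    mode: str = "permute",
) -> nx.Graph:
    """Randomize the weights of ``round(fraction * L)`` links.

    ``mode="permute"`` (default) permutes the selected links' weights
    among themselves; ``mode="resample"`` draws them with replacement
    from the selected links' weights.  Topology and unselected weights
    are untouched.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    if mode not in ("permute", "resample"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = network.copy()
    links = sorted(canonical_pair(u, v) for u, v in network.edges())
    n_pick = int(np.floor(fraction * len(links) + 0.5))
    if n_pick == 0:
        return out
    picked = [links[i] for i in rng.choice(len(links), size=n_pick, replace=False)]
    weights = np.array([out[u][v]["weight"] for u, v in picked])
    if mode == "permute":
        new = weights[rng.permutation(n_pick)]
    else:
        new = weights[rng.integers(0, n_pick, size=n_pick)]
    for (u, v), w in zip(picked, new):
        out[u][v]["weight"] = float(w)
    return out


def _mean_path_length(graph: nx.Graph) -> float:
    """Mean shortest-path length over connected node pairs (hop count)."""
    total = 0.0
    pairs = 0
    for comp in nx.connected_components(graph):
        if len(comp) < 2:
            continue
        sub = graph.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
            pairs += len(dists) - 1  # excludes the source itself
    return total / pairs if pairs else 0.0


def network_statistics(
    filtered: nx.Graph, reference_links: set[tuple[str, str]]
) -> dict[str, float]:
    """The six LWRN comparison statistics of a filtered network.

    Computed on the subgraph induced by non-isolated nodes (isolated
    nodes are the effect of complete link removal, not network members).
    A filtered network with no links yields all-zero statistics and a
    ``degenerate`` flag.
    """
    core_nodes = [n for n in filtered.nodes() if filtered.degree(n) > 0]
    links = {canonical_pair(u, v) for u, v in filtered.edges()}
    if not core_nodes:
        stats = dict.fromkeys(STATISTIC_COLUMNS, 0.0)
        stats["degenerate"] = 1.0
        return stats
    core = filtered.subgraph(core_nodes)
    node_bet = nx.betweenness_centrality(core, normalized=True)
    link_bet = nx.edge_betweenness_centrality(core, normalized=True)
    intersection = links & reference_links
    return {
        "mean_degree": 2.0 * core.number_of_edges() / core.number_of_nodes(),
        "mean_path_length": _mean_path_length(core),
        "mean_node_betweenness": float(np.mean(list(node_bet.values()))),
        "mean_link_betweenness": float(np.mean(list(link_bet.values()))),
        "mean_clustering": float(nx.average_clustering(core, count_zeros=True)),
        "intersection_count": float(len(intersection)),
        "intersection_fraction": (
            len(intersection) / len(reference_links) if reference_links else 0.0
        ),
        "degenerate": 0.0,
    }


def default_significance_pipeline(bin_width: float = 1.0) -> Callable[[nx.Graph], pd.DataFrame]:
    """Standard significance stage: empirical distribution + global-null p-values."""

    def pipeline(graph: nx.Graph) -> pd.DataFrame:
        return gloss_pvalues(graph, empirical_distribution(graph, bin_width))

    return pipeline


def lwrn_experiment(
    network: nx.Graph,
    significance_pipeline: Callable[[nx.Graph], pd.DataFrame],
    reference: FilterResult,
    constraints: list[AnchorConstraint],
    fractions: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    iterations: int = 30,
    seed: int = 0,
    mode: str = "permute",
) -> pd.DataFrame:
    """Run the full LWRN experiment.

    For every fraction and iteration: randomize weights, recompute link
    significance, re-run filtering under the same constraints, and compute
    the six statistics on the filtered copy.  Per-iteration seeds derive
    from the master seed and the (fraction, iteration) index, so runs are
    reproducible and order-independent.  Returns a tidy DataFrame with one
    row per (fraction, iteration) plus a ``"mean"`` row per fraction.
    """
    reference_links = {canonical_pair(u, v) for u, v in reference.network.edges()}
    rows = []
    for fi, fraction in enumerate(fractions):
        per_iter = []
        for it in range(iterations):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(fi, it))
            )
            lwrn = randomize_weights(network, fraction, rng, mode=mode)
            sig = significance_pipeline(lwrn)
            result = filter_network(lwrn, sig, constraints,
                                    record_topology=False)
            stats = network_statistics(result.network, reference_links)
            if stats.pop("degenerate"):
                logger.warning("degenerate filtered network at f=%.2f it=%d",
                               fraction, it)
            per_iter.append(stats)
            rows.append({"fraction": fraction, "iteration": str(it), **stats})
        mean_stats = {
            col: float(np.mean([s[col] for s in per_iter]))
            for col in STATISTIC_COLUMNS
        }
        rows.append({"fraction": fraction, "iteration": "mean", **mean_stats})
        logger.info("LWRN f=%.1f: mean intersection fraction %.3f",
                    fraction, mean_stats["intersection_fraction"])
    return pd.DataFrame(rows, columns=["fraction", "iteration", *STATISTIC_COLUMNS])
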