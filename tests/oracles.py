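"""Independent naive reference implementations used only by tests.

Each oracle recomputes a quantity with the most literal method available
(loops, enumeration, factorial formulas) so that the package's optimized
paths can be checked against it.
"""

from math import comb

import networkx as nx
import numpy as np


def naive_pearson(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.corrcoef(x, y)[0, 1])


def naive_jackknife(x, y) -> float:
    """Plain mean of the n leave-one-out Pearson correlations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    rs = []
    for i in range(x.size):
        rs.append(naive_pearson(np.delete(x, i), np.delete(y, i)))
    return float(np.mean(rs))


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability from the factorial formula."""
    total = comb(N, n)
    return sum(comb(K, x) * comb(N - K, n - x)
               for x in range(k, min(n, K) + 1)) / total


def bh_step_up(p_values):
    """Textbook Benjamini-Hochberg step-up adjustment, input order."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * m / rank)
        adjusted[i] = running
    return adjusted


def naive_topology(graph: nx.Graph, original: nx.Graph):
    """(diameter, n_rel, <s>) by direct component enumeration."""
    comps = sorted(nx.connected_components(graph), key=len, reverse=True)
    if not comps:
        return 0.0, 0.0, 0.0
    giant = graph.subgraph(comps[0])
    if giant.number_of_nodes() > 1:
        lengths = dict(nx.all_pairs_shortest_path_length(giant))
        diameter = max(max(d.values()) for d in lengths.values())
    else:
        diameter = 0
    n_rel = len(comps[0]) / original.number_of_nodes()
    others = [len(c) for c in comps[1:]]
    mean_s = float(np.mean(others)) if others else 0.0
    return float(diameter), n_rel, mean_s


def naive_mean_path_length(graph: nx.Graph) -> float:
    """Mean hop distance over all connected unordered node pairs."""
    total, pairs = 0, 0
    nodes = sorted(graph.nodes())
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            if nx.has_path(graph, u, v):
                total += nx.shortest_path_length(graph, u, v)
                pairs += 1
    return total / pairs if pairs else 0.0


def naive_clustering(graph: nx.Graph) -> float:
    """Mean local clustering, 0 for nodes of degree < 2."""
    vals = []
    for node in graph.nodes():
        nbrs = list(graph.neighbors(node))
        k = len(nbrs)
        if k < 2:
            vals.append(0.0)
            continue
        links = sum(1 for i in range(k) for j in range(i + 1, k)
                    if graph.has_edge(nbrs[i], nbrs[j]))
        vals.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(vals)) if vals else 0.0


def anchors_connected_bfs(graph: nx.Graph, set_a, set_b) -> bool:
    """Path existence by breadth-first search from every source."""
    for a in set_a:
        for b in set_b:
            if a in graph and b in graph and nx.has_path(graph, a, b):
                return True
    return False
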