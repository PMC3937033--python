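"""Connectivity-constrained descending-p-value link filtering.

Links are removed one at a time in strictly non-increasing p-value order
(ties broken by ascending weight, then lexicographic link identity).
After each removal every anchor constraint is checked: at least one path
must join the two anchor gene sets.  The first removal that breaks a
constraint is undone — the link is returned to the network — and
filtering stops.  Topology (diameter of the giant component, relative
giant size n_rel = n/N, mean isolated-component size <s>) is recorded
after every accepted removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from tppin.geneset import GeneSet
from tppin.network_io import canonical_pair


class AnchorConfigurationError(ValueError):
    """An anchor gene is absent from the network, or a constraint is
    already violated before filtering starts."""


@dataclass(frozen=True)
class AnchorConstraint:
    """Connectivity must persist between ``set_a`` and ``set_b``."""

    set_a: GeneSet
    set_b: GeneSet

    def validate(self, network: nx.Graph) -> None:
        for gs in (self.set_a, self.set_b):
            if len(gs) == 0:
                raise AnchorConfigurationError(f"anchor set {gs.name!r} is empty")
            missing = sorted(g for g in gs.members if g not in network)
            if missing:
                raise AnchorConfigurationError(
                    f"anchor genes absent from network ({gs.name!r}): {missing}"
                )


@dataclass(frozen=True)
class TopologyRecord:
    """Snapshot of network topology during filtering."""

    links_removed_fraction: float
    nodes_isolated_fraction: float
    diameter: float
    giant_relative_size: float
    mean_isolated_component_size: float


@dataclass
class FilterResult:
    """Outcome of one filtering run."""

    network: nx.Graph
    trace: pd.DataFrame  # step, gene_a, gene_b, p_value, accepted
    stop_link: tuple[str, str] | None
    topology: pd.DataFrame  # one TopologyRecord row per accepted removal
    stop_reason: str
    removed_links: list[tuple[str, str]] = field(default_factory=list)


def anchors_connected(network: nx.Graph, constraint: AnchorConstraint) -> bool:
    """True iff some path joins any member of set_a to any member of set_b."""
    constraint.validate(network)
    labels = {}
    for i, comp in enumerate(nx.connected_components(network)):
        for node in comp:
            labels[node] = i
    comps_a = {labels[g] for g in constraint.set_a.members}
    comps_b = {labels[g] for g in constraint.set_b.members}
    return bool(comps_a & comps_b)


# ---------------------------------------------------------------------------
# array-based internals (per-step checks in C via scipy.sparse.csgraph)

def _component_labels(n_nodes: int, tails, heads, active) -> np.ndarray:
    row = tails[active]
    col = heads[active]
    data = np.ones(row.size)
    adj = coo_matrix((data, (row, col)), shape=(n_nodes, n_nodes))
    _, labels = connected_components(adj, directed=False)
    return labels


def _giant_diameter(n_nodes: int, tails, heads, active, labels) -> float:
    """Longest shortest path within the largest connected component."""
    sizes = np.bincount(labels, minlength=1)
    giant = int(sizes.argmax())
    members = np.flatnonzero(labels == giant)
    if members.size <= 1:
        return 0.0
    keep = active & (labels[tails] == giant)
    remap = np.full(n_nodes, -1)
    remap[members] = np.arange(members.size)
    row, col = remap[tails[keep]], remap[heads[keep]]
    adj = coo_matrix(
        (np.ones(row.size), (row, col)), shape=(members.size, members.size)
    )
    dist = shortest_path(adj, method="D", directed=False, unweighted=True)
    return float(dist[np.isfinite(dist)].max())


def _record(n_nodes, n_links_total, tails, heads, active, labels) -> TopologyRecord:
    if n_nodes == 0:
        return TopologyRecord(0.0, 0.0, 0.0, 0.0, 0.0)
    sizes = np.bincount(labels)
    giant = int(sizes.argmax())
    degree = np.bincount(
        np.concatenate([tails[active], heads[active]]), minlength=n_nodes
    )
    isolated_nodes = int((degree == 0).sum())
    others = np.delete(sizes, giant)
    mean_isolated = float(others.mean()) if others.size else 0.0
    return TopologyRecord(
        links_removed_fraction=1.0 - active.sum() / n_links_total,
        nodes_isolated_fraction=isolated_nodes / n_nodes,
        diameter=_giant_diameter(n_nodes, tails, heads, active, labels),
        giant_relative_size=float(sizes[giant]) / n_nodes,
        mean_isolated_component_size=mean_isolated,
    )


def topology_record(network: nx.Graph, original: nx.Graph | None = None) -> TopologyRecord:
    """Topology snapshot of *network* relative to *original*.

    * diameter: longest shortest path within the largest connected
      component (0 for an empty network);
    * giant_relative_size: giant node count / original node count;
    * mean_isolated_component_size: mean size of the non-giant components,
      singletons included, 0 when only the giant exists;
    * removal fractions relative to the original link/node counts.
    """
    if original is None:
        original = network
    n_total = original.number_of_nodes()
    m_total = original.number_of_edges()
    if network.number_of_nodes() == 0 or n_total == 0:
        return TopologyRecord(0.0, 0.0, 0.0, 0.0, 0.0)
    comps = sorted(nx.connected_components(network), key=len, reverse=True)
    giant = network.subgraph(comps[0])
    diameter = float(nx.diameter(giant)) if giant.number_of_nodes() > 1 else 0.0
    others = [len(c) for c in comps[1:]]
    # nodes of the original that are absent or isolated now
    isolated = sum(
        1 for n in original.nodes()
        if n not in network or network.degree(n) == 0
    )
    m = network.number_of_edges()
    return TopologyRecord(
        links_removed_fraction=(1.0 - m / m_total) if m_total else 0.0,
        nodes_isolated_fraction=isolated / n_total,
        diameter=diameter,
        giant_relative_size=len(comps[0]) / n_total,
        mean_isolated_component_size=float(np.mean(others)) if others else 0.0,
    )


def removal_order(significance: pd.DataFrame) -> pd.DataFrame:
    """Deterministic removal order: descending p, then ascending weight,
    then lexicographic link identity."""
    return significance.sort_values(
        ["p_value", "weight", "gene_a", "gene_b"],
        ascending=[False, True, True, True],
        ignore_index=True,
    )


def filter_network(
    network: nx.Graph,
    significance: pd.DataFrame,
    constraints: list[AnchorConstraint],
    mode: str = "joint",
    record_topology: bool = True,
) -> FilterResult:
    """Run the connectivity-constrained filtering procedure.

    *significance* must hold one row per network link (``gene_a, gene_b,
    weight, p_value``).  With ``mode="joint"`` (default) all constraints
    are enforced simultaneously in a single pass; ``mode="sequential"``
    runs one pass per constraint, feeding each pass's surviving network to
    the next, and returns the last pass's result with concatenated traces.

    The input network must already satisfy every constraint.
    """
    if mode not in ("joint", "sequential"):
        raise ValueError(f"unknown mode {mode!r}")
    for constraint in constraints:
        constraint.validate(network)
        if not anchors_connected(network, constraint):
            raise AnchorConfigurationError(
                f"constraint {constraint.set_a.name!r}-{constraint.set_b.name!r} "
                "is violated before filtering starts"
            )
    if mode == "sequential" and len(constraints) > 1:
        return _filter_sequential(network, significance, constraints,
                                  record_topology)
    return _filter_joint(network, significance, constraints, record_topology)


def _filter_joint(network, significance, constraints, record_topology):
    nodes = sorted(network.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    n_nodes = len(nodes)

    order = removal_order(significance)
    pmap = {}
    for row in order.itertuples(index=False):
        pmap[canonical_pair(row.gene_a, row.gene_b)] = float(row.p_value)
    missing = [canonical_pair(u, v) for u, v in network.edges()
               if canonical_pair(u, v) not in pmap]
    if missing:
        raise ValueError(f"{len(missing)} links lack a p-value, e.g. {missing[0]}")

    links = [canonical_pair(r.gene_a, r.gene_b) for r in order.itertuples(index=False)]
    tails = np.array([index[a] for a, _ in links], dtype=np.int64)
    heads = np.array([index[b] for _, b in links], dtype=np.int64)
    active = np.ones(len(links), dtype=bool)
    n_links_total = len(links)

    anchor_idx = [
        (np.array([index[g] for g in c.set_a.members], dtype=np.int64),
         np.array([index[g] for g in c.set_b.members], dtype=np.int64))
        for c in constraints
    ]

    trace_rows = []
    topo_rows = []
    removed: list[tuple[str, str]] = []
    stop_link = None
    stop_reason = "exhausted"

    for e, (a, b) in enumerate(links):
        active[e] = False
        labels = _component_labels(n_nodes, tails, heads, active)
        ok = all(
            bool(np.intersect1d(labels[ia], labels[ib]).size)
            for ia, ib in anchor_idx
        ) if anchor_idx else True
        if not ok:
            active[e] = True
            stop_link = (a, b)
            stop_reason = "anchor disconnection"
            trace_rows.append((len(removed), a, b, pmap[(a, b)], False))
            break
        removed.append((a, b))
        trace_rows.append((len(removed) - 1, a, b, pmap[(a, b)], True))
        if record_topology:
            topo_rows.append(_record(n_nodes, n_links_total, tails, heads,
                                     active, labels))

    surviving = nx.Graph()
    surviving.add_nodes_from(nodes)
    for e in np.flatnonzero(active):
        a, b = links[e]
        surviving.add_edge(a, b, **network[a][b])
    surviving.graph.update(network.graph)

    trace = pd.DataFrame(
        trace_rows, columns=["step", "gene_a", "gene_b", "p_value", "accepted"]
    )
    topology = pd.DataFrame([vars(r) for r in topo_rows]) if topo_rows else \
        pd.DataFrame(columns=["links_removed_fraction", "nodes_isolated_fraction",
                              "diameter", "giant_relative_size",
                              "mean_isolated_component_size"])
    return FilterResult(surviving, trace, stop_link, topology, stop_reason,
                        removed)


def _filter_sequential(network, significance, constraints, record_topology):
    current = network
    sig = significance
    traces = []
    result = None
    for constraint in constraints:
        result = _filter_joint(current, sig, [constraint], record_topology)
        traces.append(result.trace)
        current = result.network
        surviving_links = {canonical_pair(u, v) for u, v in current.edges()}
        keep = sig.apply(
            lambda r: canonical_pair(r["gene_a"], r["gene_b"]) in surviving_links,
            axis=1,
        )
        sig = sig[keep].reset_index(drop=True)
    result.trace = pd.concat(traces, ignore_index=True)
    result.trace["step"] = range(len(result.trace))
    return result
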