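"""Read/write weighted networks and apply structural edge-list pre-filters.

Networks are held as :class:`networkx.Graph` objects: nodes are gene
identifiers (opaque strings), links carry a non-negative ``weight``
attribute.  Raw edge lists are cleaned on load: self-interactions are
dropped, multiple records for the same unordered gene pair are collapsed
to one link, and (optionally) links with an endpoint outside a designated
member set are removed.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import networkx as nx

from tppin.geneset import GeneSet

logger = logging.getLogger(__name__)


class EdgeListParseError(ValueError):
    """A malformed row in an edge-list file (carries the line number)."""


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Endpoints of an unordered link in lexicographic order.

    Canonical ordering gives every link a deterministic identity, which the
    filtering stage relies on for reproducible tie-breaking.
    """
    return (a, b) if a <= b else (b, a)


def load_edge_list(
    path: str | Path,
    member_set: GeneSet | None = None,
) -> nx.Graph:
    """Load a TSV edge list into a simple undirected weighted graph.

    Rows have 2 or 3 tab-separated columns: ``gene_a  gene_b  [weight]``.
    Lines starting with ``#`` are comments.  Cleaning rules:

    * self-interactions (``a == a``) are omitted;
    * duplicate records for one unordered gene pair are collapsed to a
      single link — the first record's weight wins and conflicts are logged;
    * if *member_set* is given, links with either endpoint outside it are
      dropped.

    Counts of dropped/collapsed records are stored in
    ``G.graph["load_stats"]``.
    """
    path = Path(path)
    graph = nx.Graph()
    stats = {"rows": 0, "self_loops": 0, "duplicates": 0,
             "weight_conflicts": 0, "non_member": 0}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected at least two non-empty "
                    f"tab-separated identifiers, got {line!r}"
                )
            a, b = fields[0].strip(), fields[1].strip()
            if len(fields) >= 3 and fields[2].strip():
                try:
                    weight = float(fields[2])
                except ValueError as exc:
                    raise EdgeListParseError(
                        f"{path}:{lineno}: non-numeric weight {fields[2]!r}"
                    ) from exc
                if weight < 0:
                    raise EdgeListParseError(
                        f"{path}:{lineno}: negative weight {weight}"
                    )
            else:
                weight = 1.0
            stats["rows"] += 1
            if a == b:
                stats["self_loops"] += 1
                continue
            if member_set is not None and (a not in member_set or b not in member_set):
                stats["non_member"] += 1
                continue
            u, v = canonical_pair(a, b)
            if graph.has_edge(u, v):
                stats["duplicates"] += 1
                if graph[u][v]["weight"] != weight:
                    stats["weight_conflicts"] += 1
                    logger.warning(
                        "%s:%d: conflicting weight for pair (%s, %s); "
                        "keeping first (%g, ignoring %g)",
                        path, lineno, u, v, graph[u][v]["weight"], weight,
                    )
                continue
            graph.add_edge(u, v, weight=weight)
    graph.graph["load_stats"] = stats
    logger.info(
        "loaded %d links among %d genes from %s "
        "(%d rows; dropped %d self-interactions, %d duplicates, %d non-member)",
        graph.number_of_edges(), graph.number_of_nodes(), path,
        stats["rows"], stats["self_loops"], stats["duplicates"],
        stats["non_member"],
    )
    if graph.number_of_edges() == 0:
        warnings.warn(f"edge list {path} produced an empty network", stacklevel=2)
    return graph


def write_network(
    graph: nx.Graph,
    path: str | Path,
    p_values=None,
    fmt: str | None = None,
) -> None:
    """Write a network as TSV (default) or GraphML.

    The TSV dialect round-trips losslessly through :func:`load_edge_list`
    (weights written at full float precision).  *p_values*, if given, is a link
    significance table (``gene_a``/``gene_b``/``p_value`` columns) emitted
    as an extra link attribute column.
    """
    path = Path(path)
    if fmt is None:
        fmt = "graphml" if path.suffix.lower() == ".graphml" else "tsv"
    pmap = {}
    if p_values is not None:
        for row in p_values.itertuples(index=False):
            pmap[canonical_pair(row.gene_a, row.gene_b)] = row.p_value

    if fmt == "graphml":
        out = nx.Graph()
        out.add_nodes_from(graph.nodes())
        for u, v, data in graph.edges(data=True):
            attrs = {"weight": float(data.get("weight", 1.0))}
            key = canonical_pair(u, v)
            if key in pmap:
                attrs["p_value"] = float(pmap[key])
            out.add_edge(u, v, **attrs)
        nx.write_graphml(out, path)
        return

    header = "# gene_a\tgene_b\tweight"
    if p_values is not None:
        header += "\tp_value"
    lines = [header]
    for u, v, data in sorted(graph.edges(data=True),
                             key=lambda e: canonical_pair(e[0], e[1])):
        a, b = canonical_pair(u, v)
        row = f"{a}\t{b}\t{data.get('weight', 1.0):.17g}"
        if p_values is not None:
            key = (a, b)
            row += f"\t{pmap[key]:.17g}" if key in pmap else "\t"
        lines.append(row)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    # isolated nodes are not representable in an edge list; record them
    isolates = [n for n in graph.nodes() if graph.degree(n) == 0]
    if isolates:
        logger.info("%d isolated nodes not written to %s", len(isolates), path)


def load_network(path: str | Path) -> nx.Graph:
    """Load a network written by :func:`write_network` (TSV or GraphML)."""
    path = Path(path)
    if path.suffix.lower() == ".graphml":
        graph = nx.read_graphml(path)
        return nx.relabel_nodes(graph, {n: str(n) for n in graph.nodes()})
    return load_edge_list(path)
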