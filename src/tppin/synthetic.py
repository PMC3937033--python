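"""Synthetic scenario generator.

Emulates the statistical structure the pipeline assumes, so every
downstream stage is testable without external databases:

* a sparse undirected interaction network with heavy-tailed degrees
  (preferential-attachment wiring) plus a planted backbone path joining
  three designated anchor gene sets;
* a gene-expression matrix drawn from a multivariate normal whose
  correlation matrix is block-structured (high correlation within planted
  modules, weak background correlation elsewhere) with a first-order
  autoregressive correlation chain along the backbone path, and values
  missing completely at random;
* binary essential-gene labels with planted enrichment on the backbone.

One integer seed drives all three generators deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from tppin.geneset import GeneSet
from tppin.network_io import canonical_pair

ANCHOR_NAMES = ("tcr_complex", "nfkb", "nfat")

# sub-stream labels so the three generators draw from independent,
# seed-reproducible streams
_STREAM_NETWORK = 1
_STREAM_EXPRESSION = 2
_STREAM_ANNOTATION = 3


class ScenarioParameterError(ValueError):
    """Infeasible or inconsistent scenario parameters."""


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic study scenario.

    Defaults describe the desk-scale default scenario: 200 genes measured
    in 60 samples, 800 interactions, three 4-gene anchor sets joined by a
    12-link backbone path whose genes form a high-correlation module.
    """

    n_genes: int = 200
    n_samples: int = 60
    n_links: int = 800
    module_spec: list[tuple[int, float]] = field(
        default_factory=lambda: [(25, 0.8), (25, 0.6), (25, 0.4)]
    )
    rho_out: float = 0.05
    anchor_sizes: tuple[int, int, int] = (4, 4, 4)
    backbone_length: int = 12
    backbone_rho: float = 0.9
    essential_fraction_overall: float = 0.2
    essential_fraction_backbone: float = 0.8
    missing_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_rate < 1:
            raise ScenarioParameterError("missing_rate must lie in [0, 1)")
        for frac in (self.essential_fraction_overall,
                     self.essential_fraction_backbone):
            if not 0 <= frac <= 1:
                raise ScenarioParameterError("essential fractions must lie in [0, 1]")
        rhos = [rho for _, rho in self.module_spec]
        rhos += [self.rho_out, self.backbone_rho]
        if any(not -1 <= rho <= 1 for rho in rhos):
            raise ScenarioParameterError("correlations must lie in [-1, 1]")
        n_backbone = self.backbone_length + 1
        if sum(size for size, _ in self.module_spec) + n_backbone > self.n_genes:
            raise ScenarioParameterError("module sizes exceed n_genes")
        max_links = self.n_genes * (self.n_genes - 1) // 2
        if not self.backbone_length <= self.n_links <= max_links:
            raise ScenarioParameterError(
                f"n_links must lie in [{self.backbone_length}, {max_links}]"
            )
        if self.backbone_length < 2:
            raise ScenarioParameterError(
                "backbone path needs >= 2 links to join three anchor sets"
            )
        if sum(self.anchor_sizes) + self.backbone_length + 1 > self.n_genes + 3:
            # the three anchor representatives sit on the path itself
            raise ScenarioParameterError("anchor sets do not fit in n_genes")
        if any(size < 1 for size in self.anchor_sizes):
            raise ScenarioParameterError("anchor sets must be non-empty")

    @property
    def gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes - 1)))
        return [f"G{i:0{width}d}" for i in range(self.n_genes)]

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,))
        )


def default_scenario(seed: int = 0) -> SyntheticScenario:
    """The default desk-scale scenario (200 genes x 60 samples, 800 links)."""
    return SyntheticScenario(seed=seed)


def planted_scenario(seed: int = 0) -> SyntheticScenario:
    """Larger planted-backbone scenario: 300 genes, 1500 links, 20-link backbone."""
    return SyntheticScenario(
        n_genes=300,
        n_samples=100,
        n_links=1500,
        module_spec=[(30, 0.8), (30, 0.6), (30, 0.4)],
        anchor_sizes=(5, 5, 5),
        backbone_length=20,
        seed=seed,
    )


def _planted_path(scenario: SyntheticScenario, rng: np.random.Generator):
    """Choose backbone path nodes and anchor sets.

    The path visits one representative of each anchor set (positions 0,
    middle and end); remaining anchor members are off-path genes.
    """
    genes = scenario.gene_ids
    n_path = scenario.backbone_length + 1
    perm = rng.permutation(scenario.n_genes)
    path_nodes = [genes[i] for i in perm[:n_path]]
    rep_positions = (0, n_path // 2, n_path - 1)
    off_path = [genes[i] for i in perm[n_path:]]
    anchors = {}
    cursor = 0
    for name, size, pos in zip(ANCHOR_NAMES, scenario.anchor_sizes, rep_positions):
        members = {path_nodes[pos]}
        extra = off_path[cursor:cursor + size - 1]
        cursor += size - 1
        members.update(extra)
        anchors[name] = GeneSet(name, frozenset(members))
    backbone_links = {
        canonical_pair(path_nodes[i], path_nodes[i + 1])
        for i in range(scenario.backbone_length)
    }
    return path_nodes, anchors, backbone_links


def backbone_path(graph: nx.Graph) -> list[str]:
    """Backbone path genes in path order."""
    return list(graph.graph["backbone_path"])


def generate_network(scenario: SyntheticScenario) -> nx.Graph:
    """Generate the scenario's interaction network.

    Wiring is preferential-attachment style (each new node attaches to
    existing nodes with probability proportional to degree), giving a
    heavy-tailed degree sequence; the planted backbone path is then added
    and the link count adjusted to exactly ``n_links`` (never touching
    backbone links).  Graph metadata: ``G.graph["anchor_sets"]`` (name ->
    sorted member list), ``G.graph["backbone_links"]`` and
    ``G.graph["backbone_nodes"]``; backbone links also carry a
    ``backbone=True`` attribute.  All weights are initialised to 1.0 —
    real weights come from the correlation stage.
    """
    rng = scenario._rng(_STREAM_NETWORK)
    genes = scenario.gene_ids
    path_nodes, anchors, backbone_links = _planted_path(scenario, rng)

    m = max(1, round(scenario.n_links / scenario.n_genes))
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    order = [genes[i] for i in rng.permutation(scenario.n_genes)]
    # degree-proportional target sampling via a repeated-nodes urn
    urn: list[str] = list(order[: m + 1])
    for i in range(1, min(m + 1, len(order))):
        graph.add_edge(*canonical_pair(order[0], order[i]), weight=1.0)
    for v in order[m + 1:]:
        # ordered container: iteration order must not depend on hashing
        targets: list[str] = []
        while len(targets) < m:
            t = urn[rng.integers(len(urn))]
            if t not in targets:
                targets.append(t)
        for t in targets:
            graph.add_edge(*canonical_pair(v, t), weight=1.0)
            urn.append(t)
        urn.extend([v] * m)

    for u, v in backbone_links:
        graph.add_edge(u, v, weight=1.0)

    # top up or trim to the exact link count
    while graph.number_of_edges() < scenario.n_links:
        u = urn[rng.integers(len(urn))]
        v = urn[rng.integers(len(urn))]
        if u != v and not graph.has_edge(u, v):
            graph.add_edge(*canonical_pair(u, v), weight=1.0)
            urn.extend([u, v])
    if graph.number_of_edges() > scenario.n_links:
        removable = sorted(
            canonical_pair(u, v)
            for u, v in graph.edges()
            if canonical_pair(u, v) not in backbone_links
        )
        excess = graph.number_of_edges() - scenario.n_links
        if excess > len(removable):
            raise ScenarioParameterError(
                "n_links too small for the requested backbone"
            )
        for idx in rng.choice(len(removable), size=excess, replace=False):
            graph.remove_edge(*removable[idx])

    for u, v in backbone_links:
        graph[u][v]["backbone"] = True
    graph.graph["anchor_sets"] = {
        name: sorted(gs.members) for name, gs in anchors.items()
    }
    graph.graph["backbone_links"] = sorted(backbone_links)
    graph.graph["backbone_nodes"] = sorted(path_nodes)
    graph.graph["backbone_path"] = list(path_nodes)
    return graph


def anchor_sets(graph: nx.Graph) -> dict[str, GeneSet]:
    """Recover the anchor :class:`GeneSet` objects from graph metadata."""
    return {
        name: GeneSet(name, frozenset(members))
        for name, members in graph.graph["anchor_sets"].items()
    }


def backbone_link_set(graph: nx.Graph) -> set[tuple[str, str]]:
    return {tuple(link) for link in graph.graph["backbone_links"]}


def _module_assignment(scenario: SyntheticScenario, graph: nx.Graph):
    """Assign non-backbone genes to block-correlation modules."""
    backbone = set(graph.graph["backbone_nodes"])
    rest = [g for g in scenario.gene_ids if g not in backbone]
    modules = []
    cursor = 0
    for size, rho in scenario.module_spec:
        modules.append((rest[cursor:cursor + size], rho))
        cursor += size
    return modules


def correlation_matrix(scenario: SyntheticScenario, graph: nx.Graph) -> np.ndarray:
    """Target gene-gene correlation matrix.

    Block value ``rho_in`` within each planted module and ``rho_out``
    elsewhere; along the planted backbone path the correlation is a
    first-order autoregressive chain, ``backbone_rho ** d`` for genes *d*
    path steps apart (floored at ``rho_out``).  The chain makes the path
    links themselves heavy without surrounding the path with an equally
    heavy clique — a planted *path*, not a planted module.
    """
    index = {g: i for i, g in enumerate(scenario.gene_ids)}
    n = scenario.n_genes
    corr = np.full((n, n), scenario.rho_out)
    for members, rho in _module_assignment(scenario, graph):
        idx = np.array([index[g] for g in members], dtype=int)
        corr[np.ix_(idx, idx)] = rho
    path = backbone_path(graph)
    for i in range(len(path)):
        for j in range(i + 1, len(path)):
            rho = max(scenario.backbone_rho ** (j - i), scenario.rho_out)
            corr[index[path[i]], index[path[j]]] = rho
            corr[index[path[j]], index[path[i]]] = rho
    np.fill_diagonal(corr, 1.0)
    return corr


def generate_expression(
    scenario: SyntheticScenario, graph: nx.Graph
) -> pd.DataFrame:
    """Generate the genes x samples expression matrix.

    Rows follow a multivariate normal with the block correlation matrix of
    :func:`correlation_matrix`; entries are then masked missing (NaN)
    completely at random at ``missing_rate``.  Raises
    :class:`ScenarioParameterError` if the requested correlation matrix is
    not positive semi-definite.
    """
    rng = scenario._rng(_STREAM_EXPRESSION)
    corr = correlation_matrix(scenario, graph)
    eigval, eigvec = np.linalg.eigh(corr)
    if eigval.min() < -1e-8:
        raise ScenarioParameterError(
            f"block correlation matrix is not positive semi-definite "
            f"(min eigenvalue {eigval.min():.3g})"
        )
    factor = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    z = rng.standard_normal((scenario.n_genes, scenario.n_samples))
    values = factor @ z
    if scenario.missing_rate > 0:
        mask = rng.random(values.shape) < scenario.missing_rate
        values = np.where(mask, np.nan, values)
    samples = [f"S{j:03d}" for j in range(scenario.n_samples)]
    return pd.DataFrame(values, index=scenario.gene_ids, columns=samples)


def generate_annotations(
    scenario: SyntheticScenario, graph: nx.Graph
) -> pd.DataFrame:
    """Label genes essential (1) / non-essential (0).

    Backbone genes are essential with probability
    ``essential_fraction_backbone``, all other genes with
    ``essential_fraction_overall``.
    """
    rng = scenario._rng(_STREAM_ANNOTATION)
    backbone = set(graph.graph["backbone_nodes"])
    draws = rng.random(scenario.n_genes)
    labels = [
        int(u < (scenario.essential_fraction_backbone if g in backbone
                 else scenario.essential_fraction_overall))
        for g, u in zip(scenario.gene_ids, draws)
    ]
    return pd.DataFrame({"gene": scenario.gene_ids, "is_essential": labels})


def write_scenario(scenario: SyntheticScenario, outdir: str | Path) -> dict[str, Path]:
    """Generate and write all scenario artifacts; returns the path map.

    Files: ``edges.tsv`` (edge list), ``expression.tsv`` (genes x samples,
    missing cells empty), one ``anchors_<name>.txt`` per anchor set,
    ``annotations.tsv`` (gene, is_essential), ``backbone_links.tsv`` and a
    ``scenario.yaml`` manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    graph = generate_network(scenario)
    expr = generate_expression(scenario, graph)
    annot = generate_annotations(scenario, graph)

    paths = {"edges": outdir / "edges.tsv",
             "expression": outdir / "expression.tsv",
             "annotations": outdir / "annotations.tsv",
             "backbone": outdir / "backbone_links.tsv",
             "manifest": outdir / "scenario.yaml"}
    with open(paths["edges"], "w") as fh:
        fh.write("# gene_a\tgene_b\n")
        for u, v in sorted(canonical_pair(*e) for e in graph.edges()):
            fh.write(f"{u}\t{v}\n")
    expr.to_csv(paths["expression"], sep="\t", index_label="gene",
                float_format="%.12g", na_rep="")
    annot.to_csv(paths["annotations"], sep="\t", index=False)
    with open(paths["backbone"], "w") as fh:
        fh.write("# gene_a\tgene_b\n")
        for u, v in graph.graph["backbone_links"]:
            fh.write(f"{u}\t{v}\n")
    for name, gs in anchor_sets(graph).items():
        p = outdir / f"anchors_{name}.txt"
        gs.to_file(p)
        paths[f"anchors_{name}"] = p
    manifest = {
        "n_genes": scenario.n_genes,
        "n_samples": scenario.n_samples,
        "n_links": scenario.n_links,
        "module_spec": [list(m) for m in scenario.module_spec],
        "rho_out": scenario.rho_out,
        "anchor_sizes": list(scenario.anchor_sizes),
        "backbone_length": scenario.backbone_length,
        "backbone_rho": scenario.backbone_rho,
        "essential_fraction_overall": scenario.essential_fraction_overall,
        "essential_fraction_backbone": scenario.essential_fraction_backbone,
        "missing_rate": scenario.missing_rate,
        "seed": scenario.seed,
    }
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return paths


def scenario_from_manifest(path: str | Path) -> SyntheticScenario:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    data["module_spec"] = [tuple(m) for m in data["module_spec"]]
    data["anchor_sizes"] = tuple(data["anchor_sizes"])
    return SyntheticScenario(**data)
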