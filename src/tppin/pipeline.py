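"""Pipeline orchestration: chained stages over one scenario directory.

Each stage reads its inputs from files, writes its TSV/GraphML artifacts
into the output directory, and contributes its counts to a run manifest,
so a whole run is reproducible from the manifest alone.  The command-line
interface and the numbered analysis scripts are thin wrappers over the
stage functions defined here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

import tppin
from tppin import correlation, enrichment, filtering, gloss, network_io, robustness
from tppin.geneset import GeneSet
from tppin.network_io import canonical_pair
from tppin.synthetic import SyntheticScenario, write_scenario

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.17g"  # full precision: stage outputs must round-trip exactly


@dataclass
class PipelineConfig:
    """Shared configuration of the pipeline stages.

    Defaults reproduce the study settings: expression filter at 80%
    presence, weights scaled x100, unit significance bins, joint anchor
    constraints, link-weight randomization at fractions 0.1-0.9 with 30
    iterations.
    """

    workdir: str = "results/pipeline"
    edges: str | None = None
    expression: str | None = None
    anchors: dict[str, str] = field(default_factory=dict)
    annotations: str | None = None
    min_expressed_fraction: float = 0.8
    weight_scale: float = 100.0
    bin_width: float = 1.0
    mode: str = "joint"
    lwrn_fractions: list[float] = field(
        default_factory=lambda: [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]
    )
    lwrn_iterations: int = 30
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def resolve(self, key: str, default_name: str) -> Path:
        value = getattr(self, key)
        return Path(value) if value else Path(self.workdir) / default_name


def _write_df(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def stage_simulate(scenario: SyntheticScenario, config: PipelineConfig) -> dict:
    paths = write_scenario(scenario, config.workdir)
    config.edges = str(paths["edges"])
    config.expression = str(paths["expression"])
    config.annotations = str(paths["annotations"])
    config.anchors = {
        name.removeprefix("anchors_"): str(p)
        for name, p in paths.items() if name.startswith("anchors_")
    }
    return {"stage": "simulate", "n_genes": scenario.n_genes,
            "n_links": scenario.n_links, "seed": scenario.seed}


def stage_build(config: PipelineConfig) -> tuple[nx.Graph, dict]:
    graph = network_io.load_edge_list(config.resolve("edges", "edges.tsv"))
    stats = graph.graph.get("load_stats", {})
    out = Path(config.workdir) / "network_raw.tsv"
    network_io.write_network(graph, out)
    return graph, {"stage": "build", "nodes": graph.number_of_nodes(),
                   "links": graph.number_of_edges(), **stats}


def stage_correlate(
    graph: nx.Graph, config: PipelineConfig
) -> tuple[nx.Graph, dict]:
    expr = pd.read_csv(config.resolve("expression", "expression.tsv"),
                       sep="\t", index_col=0, float_precision="round_trip")
    n_before = len(expr)
    expr = correlation.filter_expressed_genes(expr, config.min_expressed_fraction)
    result = correlation.weigh_network(graph, expr, scale=config.weight_scale)
    _write_df(result.table, Path(config.workdir) / "weights.tsv")
    network_io.write_network(result.network,
                             Path(config.workdir) / "network_weighted.tsv")
    info = {"stage": "correlate",
            "genes_before_expression_filter": n_before,
            "genes_after_expression_filter": len(expr),
            "links_weighted": result.network.number_of_edges(),
            "links_dropped_unexpressed": result.dropped_unexpressed,
            "links_dropped_undefined": result.dropped_undefined}
    return result.network, info


def stage_significance(
    graph: nx.Graph, config: PipelineConfig
) -> tuple[pd.DataFrame, dict]:
    dist = gloss.empirical_distribution(graph, config.bin_width)
    sig = gloss.gloss_pvalues(graph, dist)
    _write_df(sig, Path(config.workdir) / "significance.tsv")
    return sig, {"stage": "significance",
                 "links": len(sig),
                 "support_bins": len(dist.probs),
                 "fallback_links": int((sig["flags"] == "fallback").sum())}


def load_constraints(config: PipelineConfig) -> list[filtering.AnchorConstraint]:
    """Anchor constraints: the first anchor set (receptor complex) against
    each downstream set, enforced per the configured mode."""
    sets = {name: GeneSet.from_file(path, name)
            for name, path in sorted(config.anchors.items())}
    if len(sets) < 2:
        raise filtering.AnchorConfigurationError(
            "need at least two anchor sets for a connectivity constraint"
        )
    names = sorted(sets)
    primary = "tcr_complex" if "tcr_complex" in sets else names[0]
    return [filtering.AnchorConstraint(sets[primary], sets[name])
            for name in names if name != primary]


def stage_filter(
    graph: nx.Graph, sig: pd.DataFrame, config: PipelineConfig
) -> tuple[filtering.FilterResult, dict]:
    constraints = load_constraints(config)
    result = filtering.filter_network(graph, sig, constraints, mode=config.mode)
    workdir = Path(config.workdir)
    network_io.write_network(result.network, workdir / "network_filtered.tsv",
                             p_values=sig)
    network_io.write_network(result.network, workdir / "network_filtered.graphml",
                             p_values=sig)
    _write_df(result.trace, workdir / "removal_trace.tsv")
    _write_df(result.topology, workdir / "topology_series.tsv")
    core_nodes = sum(1 for n in result.network if result.network.degree(n) > 0)
    return result, {
        "stage": "filter",
        "links_removed": len(result.removed_links),
        "links_surviving": result.network.number_of_edges(),
        "nodes_surviving": core_nodes,
        "stop_reason": result.stop_reason,
        "stop_link": list(result.stop_link) if result.stop_link else None,
    }


def stage_robustness(
    graph: nx.Graph, reference: filtering.FilterResult, config: PipelineConfig
) -> tuple[pd.DataFrame, dict]:
    constraints = load_constraints(config)
    report = robustness.lwrn_experiment(
        graph,
        robustness.default_significance_pipeline(config.bin_width),
        reference,
        constraints,
        fractions=tuple(config.lwrn_fractions),
        iterations=config.lwrn_iterations,
        seed=config.seed,
    )
    _write_df(report, Path(config.workdir) / "lwrn_report.tsv")
    means = report[report["iteration"] == "mean"]
    return report, {
        "stage": "robustness",
        "fractions": list(config.lwrn_fractions),
        "iterations": config.lwrn_iterations,
        "mean_intersection_fraction": {
            f"{row.fraction:.1f}": round(row.intersection_fraction, 6)
            for row in means.itertuples(index=False)
        },
    }


def stage_enrich(
    weighted: nx.Graph, result: filtering.FilterResult, config: PipelineConfig
) -> tuple[pd.DataFrame, dict]:
    labels = pd.read_csv(config.resolve("annotations", "annotations.tsv"), sep="\t")
    if {"phenotype", "annotation_type"} <= set(labels.columns):
        essential = enrichment.essential_gene_filter(labels)
        annotated_genes = set(labels["gene"])
    else:
        essential = enrichment.essential_set_from_labels(labels)
        annotated_genes = set(labels["gene"])
    universe = GeneSet("annotated_network_genes",
                       frozenset(weighted.nodes()) & annotated_genes)
    core = GeneSet("filtered_core", frozenset(
        n for n in result.network if result.network.degree(n) > 0
    ))
    table = enrichment.enrich_collection(universe, essential, [core])
    _write_df(table, Path(config.workdir) / "enrichment.tsv")
    row = table.iloc[0]
    return table, {
        "stage": "enrich",
        "universe": int(row.universe_size),
        "annotated": int(row.annotated_in_universe),
        "core_genes": int(row.sample_size),
        "overlap": int(row.overlap),
        "expected": round(float(row.expected), 6),
        "p_value": float(row.p_value),
    }


def run_all(
    config: PipelineConfig, scenario: SyntheticScenario | None = None
) -> dict:
    """Chain every stage; returns the manifest dictionary.

    With *scenario* given, inputs are generated first; otherwise the
    configured input paths are used.  The manifest (config echo, seed,
    version, per-stage counts) is written to ``<workdir>/manifest.yaml``.
    """
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    stages = []
    if scenario is not None:
        stages.append(stage_simulate(scenario, config))
    graph, info = stage_build(config)
    stages.append(info)
    weighted, info = stage_correlate(graph, config)
    stages.append(info)
    sig, info = stage_significance(weighted, config)
    stages.append(info)
    result, info = stage_filter(weighted, sig, config)
    stages.append(info)
    _, info = stage_robustness(weighted, result, config)
    stages.append(info)
    _, info = stage_enrich(weighted, result, config)
    stages.append(info)
    manifest = {
        "tppin_version": tppin.__version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": stages,
    }
    with open(workdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
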