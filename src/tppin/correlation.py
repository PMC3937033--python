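"""Jackknife Pearson correlation weighting of network links.

For each pair of interacting genes the weight is the absolute value of the
mean jackknife Pearson correlation: the plain average of the n
leave-one-sample-out Pearson coefficients, computed over pairwise-complete
samples.  Weights are optionally scaled (default x100) so that link
weights live on an integer-resolution support for the significance stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from tppin.network_io import canonical_pair

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Fewer than 4 pairwise-complete samples for a gene pair."""


class UndefinedCorrelationError(ValueError):
    """A leave-one-out subset has zero variance in one of the genes."""


class EmptyExpressionError(ValueError):
    """A filtering step removed every gene."""


def expressed_fraction(expr: pd.DataFrame) -> pd.Series:
    """Per-gene fraction of non-missing samples."""
    return expr.notna().mean(axis=1)


def filter_expressed_genes(expr: pd.DataFrame, min_fraction: float = 0.8) -> pd.DataFrame:
    """Keep genes observed in at least ``min_fraction`` of samples.

    The boundary is inclusive (a gene present in exactly 80% of samples
    survives the default threshold).  Gene order is preserved.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must lie in (0, 1]")
    keep = expressed_fraction(expr) >= min_fraction
    if not keep.any():
        raise EmptyExpressionError(
            f"no gene is expressed in >= {min_fraction:.0%} of samples"
        )
    dropped = int((~keep).sum())
    if dropped:
        logger.info("expression filter: dropped %d of %d genes below %.0f%%",
                    dropped, len(keep), 100 * min_fraction)
    return expr.loc[keep]


def jackknife_correlation(x, y) -> tuple[float, int]:
    """Mean leave-one-out Pearson correlation of two sample vectors.

    Missing values are removed pairwise-complete first.  Returns
    ``(mean_r, n_effective)`` where ``mean_r = (1/n) * sum_i r_(-i)`` and
    ``r_(-i)`` is the Pearson correlation with sample *i* deleted.

    Raises :class:`InsufficientDataError` when fewer than 4 complete pairs
    remain and :class:`UndefinedCorrelationError` when any leave-one-out
    subset has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise InsufficientDataError(
            f"need >= 4 pairwise-complete samples, got {n}"
        )
    # closed-form leave-one-out moments
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    lx, ly = sx - x, sy - y
    cov = (sxy - x * y) - lx * ly / (n - 1)
    varx = (sxx - x * x) - lx * lx / (n - 1)
    vary = (syy - y * y) - ly * ly / (n - 1)
    scale = np.sqrt(np.maximum(varx, 0.0) * np.maximum(vary, 0.0))
    tiny = 1e-12 * max(sxx, syy, 1.0)
    if np.any(varx <= tiny) or np.any(vary <= tiny):
        raise UndefinedCorrelationError(
            "zero variance in a leave-one-out subset"
        )
    r_loo = np.clip(cov / scale, -1.0, 1.0)
    return float(r_loo.mean()), int(n)


@dataclass
class WeighResult:
    """Weighted network plus the per-pair correlation table."""

    network: nx.Graph
    table: pd.DataFrame  # gene_a, gene_b, mean_r, weight, scaled_weight, n_effective
    dropped_unexpressed: int
    dropped_undefined: int


def weigh_network(
    network: nx.Graph,
    expr: pd.DataFrame,
    scale: float = 100.0,
) -> WeighResult:
    """Attach jackknife-correlation weights to every network link.

    The surviving link weight is ``scale * |mean_r|``.  Links with an
    endpoint absent from the (filtered) expression matrix, or whose
    correlation is undefined / has insufficient data, are dropped and
    counted.  Zero-weight links are retained — downstream filtering is by
    p-value, not weight.
    """
    expressed = set(expr.index)
    values = {g: expr.loc[g].to_numpy(dtype=float) for g in expr.index}
    out = nx.Graph()
    out.add_nodes_from(n for n in network.nodes() if n in expressed)
    rows = []
    dropped_unexpressed = dropped_undefined = 0
    for u, v, data in network.edges(data=True):
        a, b = canonical_pair(u, v)
        if a not in expressed or b not in expressed:
            dropped_unexpressed += 1
            continue
        try:
            mean_r, n_eff = jackknife_correlation(values[a], values[b])
        except (InsufficientDataError, UndefinedCorrelationError):
            dropped_undefined += 1
            continue
        weight = abs(mean_r)
        attrs = {"weight": scale * weight, "mean_r": mean_r}
        if data.get("backbone"):
            attrs["backbone"] = True
        out.add_edge(a, b, **attrs)
        rows.append((a, b, mean_r, weight, scale * weight, n_eff))
    table = pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "mean_r", "weight",
                 "scaled_weight", "n_effective"],
    ).sort_values(["gene_a", "gene_b"], ignore_index=True)
    out.graph.update(network.graph)
    logger.info(
        "weighted %d links (%d dropped: unexpressed endpoint; "
        "%d dropped: undefined correlation)",
        out.number_of_edges(), dropped_unexpressed, dropped_undefined,
    )
    return WeighResult(out, table, dropped_unexpressed, dropped_undefined)
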