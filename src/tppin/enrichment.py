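"""Hypergeometric over-representation analysis with BH correction.

Used for the essential-gene (lethality) enrichment of the filtered core
network, and generically for any annotation gene-set collection.  The
test is one-sided (over-representation): with a universe of N genes of
which K are annotated, a sample of n genes containing k annotated ones
has

    p = sum_{x=k}^{min(n,K)} C(K,x) C(N-K,n-x) / C(N,n),

identical to a one-sided Fisher exact test on the 2x2 table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from tppin.geneset import GeneSet

logger = logging.getLogger(__name__)


class EnrichmentConfigurationError(ValueError):
    """Empty universe or empty sample after intersection."""


@dataclass(frozen=True)
class EnrichmentResult:
    """Over-representation summary for one gene set."""

    name: str
    universe_size: int        # N
    annotated_in_universe: int  # K
    sample_size: int          # n
    overlap: int              # k
    expected: float           # n*K/N
    p_value: float
    adjusted_p: float | None = None


def hypergeom_enrichment(
    universe: GeneSet,
    annotated: GeneSet,
    sample: GeneSet,
    alternative: str = "greater",
) -> EnrichmentResult:
    """Hypergeometric over-representation of *annotated* within *sample*.

    Annotated and sample genes outside the universe are dropped (and
    logged) before testing.  ``alternative="two-sided"`` switches to the
    two-sided Fisher exact p-value.
    """
    if len(universe) == 0:
        raise EnrichmentConfigurationError("empty universe")
    uni = universe.members
    ann = annotated.members & uni
    sam = sample.members & uni
    dropped = len(sample.members) - len(sam)
    if dropped:
        logger.info("enrichment %r: dropped %d sample genes outside the universe",
                    sample.name, dropped)
    if not sam:
        raise EnrichmentConfigurationError(
            f"sample {sample.name!r} is empty after intersection with the universe"
        )
    N, K, n = len(uni), len(ann), len(sam)
    k = len(ann & sam)
    if alternative == "greater":
        # upper tail Pr(X >= k); sf(k-1) is exact on the integer support
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
    elif alternative == "two-sided":
        table = [[k, n - k], [K - k, N - K - (n - k)]]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return EnrichmentResult(
        name=sample.name,
        universe_size=N,
        annotated_in_universe=K,
        sample_size=n,
        overlap=k,
        expected=n * K / N,
        p_value=min(p, 1.0),
    )


def bh_adjust(p_values) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p_values = list(p_values)
    if not p_values:
        return []
    if any(not 0 <= p <= 1 for p in p_values):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p_values, method="fdr_bh")[1])


def enrich_collection(
    universe: GeneSet,
    annotated: GeneSet,
    samples: list[GeneSet],
    alternative: str = "greater",
) -> pd.DataFrame:
    """Test each gene set in *samples* and BH-adjust across the collection."""
    results = [hypergeom_enrichment(universe, annotated, s, alternative)
               for s in samples]
    adjusted = bh_adjust([r.p_value for r in results])
    rows = []
    for res, adj in zip(results, adjusted):
        row = vars(res).copy()
        row["adjusted_p"] = adj
        rows.append(row)
    return pd.DataFrame(rows)


def essential_gene_filter(annotations: pd.DataFrame) -> GeneSet:
    """Select essential (lethality) genes from phenotype annotation rows.

    Expects columns ``gene``, ``phenotype`` and ``annotation_type``.  A
    gene qualifies when its phenotype contains the word "lethality"
    (case-insensitive substring) and its annotation type contains neither
    "partial" nor "wean".  A gene with several annotation rows qualifies
    if any row does.
    """
    required = {"gene", "phenotype", "annotation_type"}
    if not required <= set(annotations.columns):
        raise ValueError(f"annotation table needs columns {sorted(required)}")
    phen = annotations["phenotype"].astype(str).str.lower()
    atype = annotations["annotation_type"].astype(str).str.lower()
    keep = phen.str.contains("lethality") & \
        ~atype.str.contains("partial") & ~atype.str.contains("wean")
    return GeneSet("essential", frozenset(annotations.loc[keep, "gene"]))


def essential_set_from_labels(labels: pd.DataFrame) -> GeneSet:
    """Essential gene set from a binary-label table (gene, is_essential)."""
    keep = labels["is_essential"].astype(int) == 1
    return GeneSet("essential", frozenset(labels.loc[keep, "gene"]))
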