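"""Weigh network links by gene-expression correlation.

Keeps genes observed in at least 80% of samples, computes the mean
jackknife Pearson correlation for every interacting pair, and attaches
100 x |mean r| as the link weight (weights.tsv, network_weighted.tsv).
"""

from common import config_for, parse_args
from tppin import network_io
from tppin.pipeline import stage_correlate


def main() -> None:
    args = parse_args(__doc__)
    config = config_for(args)
    graph = network_io.load_network(f"{config.workdir}/network_raw.tsv")
    _, info = stage_correlate(graph, config)
    print(f"expression filter kept {info['genes_after_expression_filter']}"
          f"/{info['genes_before_expression_filter']} genes; "
          f"{info['links_weighted']} links weighted "
          f"({info['links_dropped_unexpressed']} dropped for unexpressed "
          f"endpoints, {info['links_dropped_undefined']} for undefined "
          f"correlation)")


if __name__ == "__main__":
    main()
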