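"""Score every link's statistical significance under the global null.

The null keeps the topology fixed and draws weights i.i.d. from the
network's empirical weight distribution; each link's p-value is the
conditional tail probability of its weight given both endpoint strengths
(significance.tsv).
"""

from common import config_for, parse_args
from tppin import network_io
from tppin.pipeline import stage_significance


def main() -> None:
    args = parse_args(__doc__)
    config = config_for(args)
    graph = network_io.load_network(f"{config.workdir}/network_weighted.tsv")
    _, info = stage_significance(graph, config)
    print(f"computed p-values for {info['links']} links on a "
          f"{info['support_bins']}-bin weight support "
          f"({info['fallback_links']} fallback links)")


if __name__ == "__main__":
    main()
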