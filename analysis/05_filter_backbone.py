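"""Extract the core network by connectivity-constrained filtering.

Removes links in descending p-value order while the anchor gene sets
(receptor complex vs each downstream signalling set) remain connected;
the first removal that breaks a constraint is undone and filtering
stops.  Writes the surviving network, the removal trace, and the
topology series (diameter, relative giant size, mean isolated-component
size after every accepted removal).
"""

import pandas as pd

from common import config_for, parse_args
from tppin import network_io
from tppin.pipeline import stage_filter


def main() -> None:
    args = parse_args(__doc__)
    config = config_for(args)
    graph = network_io.load_network(f"{config.workdir}/network_weighted.tsv")
    sig = pd.read_csv(f"{config.workdir}/significance.tsv", sep="\t",
                      keep_default_na=False, float_precision="round_trip")
    _, info = stage_filter(graph, sig, config)
    print(f"filtering removed {info['links_removed']} links; core network: "
          f"{info['nodes_surviving']} connected genes, "
          f"{info['links_surviving']} links; stopped on "
          f"{info['stop_reason']} at link {info['stop_link']}")


if __name__ == "__main__":
    main()
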