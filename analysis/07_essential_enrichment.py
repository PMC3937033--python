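"""Test essential-gene over-representation in the filtered core network.

Hypergeometric upper-tail test of the essential (lethality) genes among
the core network's genes, against the universe of annotated network
genes (enrichment.tsv).
"""

import pandas as pd

from common import config_for, parse_args
from tppin import filtering, network_io
from tppin.pipeline import stage_enrich


def main() -> None:
    args = parse_args(__doc__)
    config = config_for(args)
    weighted = network_io.load_network(f"{config.workdir}/network_weighted.tsv")
    filtered = network_io.load_network(f"{config.workdir}/network_filtered.tsv")
    result = filtering.FilterResult(
        network=filtered, trace=pd.DataFrame(), stop_link=None,
        topology=pd.DataFrame(), stop_reason="loaded",
    )
    _, info = stage_enrich(weighted, result, config)
    print(f"core network: {info['core_genes']} genes, {info['overlap']} "
          f"essential (expected {info['expected']:.1f} of "
          f"{info['annotated']} annotated in a universe of "
          f"{info['universe']}); hypergeometric p = {info['p_value']:.3g}")


if __name__ == "__main__":
    main()
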