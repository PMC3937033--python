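"""Load and clean the raw interaction edge list.

Collapses duplicate records, drops self-interactions, and writes the
cleaned network (network_raw.tsv).
"""

from common import config_for, parse_args
from tppin.pipeline import stage_build


def main() -> None:
    args = parse_args(__doc__)
    _, info = stage_build(config_for(args))
    print(f"built network: {info['nodes']} nodes, {info['links']} links "
          f"({info.get('self_loops', 0)} self-interactions and "
          f"{info.get('duplicates', 0)} duplicates dropped)")


if __name__ == "__main__":
    main()
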