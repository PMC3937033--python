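"""Generate the synthetic study inputs.

Writes an interaction edge list, a block-correlated expression matrix
with a planted backbone path joining three anchor gene sets, essential-
gene labels and the anchor-set files into the work directory.
"""

from pathlib import Path

from common import config_for, parse_args
from tppin.pipeline import stage_simulate
from tppin.synthetic import default_scenario


def main() -> None:
    args = parse_args(__doc__)
    config = config_for(args)
    Path(config.workdir).mkdir(parents=True, exist_ok=True)
    scenario = default_scenario(seed=args.seed)
    info = stage_simulate(scenario, config)
    print(f"simulated scenario: {info['n_genes']} genes, "
          f"{info['n_links']} interactions, seed {info['seed']}; "
          f"inputs written to {config.workdir}")


if __name__ == "__main__":
    main()
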