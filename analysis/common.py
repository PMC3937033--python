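"""Shared plumbing for the numbered analysis drivers."""

import argparse
from pathlib import Path

from tppin.pipeline import PipelineConfig


def parse_args(description: str) -> argparse.Namespace:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--workdir", default="results/pipeline",
                        help="shared stage directory (default: results/pipeline)")
    parser.add_argument("--seed", type=int, default=0, help="master seed")
    return parser.parse_args()


def config_for(args: argparse.Namespace) -> PipelineConfig:
    """Pipeline configuration bound to the workdir; anchor-set files
    written by the simulation step are auto-discovered."""
    workdir = Path(args.workdir)
    anchors = {p.stem.removeprefix("anchors_"): str(p)
               for p in sorted(workdir.glob("anchors_*.txt"))}
    return PipelineConfig(workdir=str(workdir), seed=args.seed, anchors=anchors)
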