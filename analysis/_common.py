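"""Shared plumbing for the numbered analysis scripts."""

import argparse
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from skimrepeats.pipeline import RunConfig  # noqa: E402


def parse_args(description):
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--outdir", default="results/run")
    parser.add_argument("--config", default=None)
    return parser.parse_args()


def load_config(args):
    cfg = RunConfig.from_yaml(args.config) if args.config else RunConfig()
    cfg.seed = args.seed
    cfg.outdir = args.outdir
    return cfg
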