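"""Shared argument parsing for the numbered analysis scripts."""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from optoburst.cli import validate_config  # noqa: E402

DEFAULT_CONFIG = Path(__file__).parent / "config.yaml"


def parse(description: str):
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--config", default=str(DEFAULT_CONFIG))
    parser.add_argument("--outdir", default=None)
    parser.add_argument("--seed", type=int, default=None)
    args = parser.parse_args()
    cfg = validate_config(args.config)
    if args.seed is not None:
        cfg["seed"] = args.seed
    return cfg, args.outdir
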