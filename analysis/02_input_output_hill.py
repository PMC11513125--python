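#!/usr/bin/env python
"""Input-output analysis: binned mean transcription rate vs repressor
concentration with a weighted Hill fit, plus the fraction-active
timecourse. Requires the trace set from 01_simulate.py."""

import yaml

from _common import parse

from optoburst.cli import cmd_analyze


def main():
    cfg, outdir = parse(__doc__)
    out = cmd_analyze(cfg, outdir=outdir)
    meta = yaml.safe_load((out / "analysis.yaml").read_text())
    fit = meta["hill_fit"]
    print(
        f"Hill fit: H = {fit['H']:.2f} +/- {fit['se']['H']:.2f}, "
        f"K_D = {fit['K_D']:.2f} +/- {fit['se']['K_D']:.2f} au"
    )


if __name__ == "__main__":
    main()
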