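#!/usr/bin/env python
"""Compound-HMM burst-parameter inference on low- and high-repressor
trace segments with a nucleus-level bootstrap. Requires the trace set
from 01_simulate.py. This is the slowest stage (tens of minutes at the
default bootstrap settings; reduce bursts.n_boot to shorten)."""

import pandas as pd

from _common import parse

from optoburst.cli import cmd_infer_bursts


def main():
    cfg, outdir = parse(__doc__)
    out = cmd_infer_bursts(cfg, outdir=outdir)
    res = pd.read_csv(out / "burst_params.csv")
    for _, row in res.iterrows():
        print(
            f"{row['group']}: k_on = {row['k_on_per_min']:.2f} "
            f"+/- {row['k_on_se']:.2f} /min, "
            f"duration = {row['duration_min']:.2f} min"
        )


if __name__ == "__main__":
    main()
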