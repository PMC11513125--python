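#!/usr/bin/env python
"""Simulation-based MCMC over the microscopic burst-frequency response
parameters (kon0, K_D, H): coarse sweep, Metropolis-Hastings sampling
with common random numbers, posterior summaries and best-25
realizations. Requires the trace set from 01_simulate.py."""

import yaml

from _common import parse

from optoburst.cli import cmd_infer_io


def main():
    cfg, outdir = parse(__doc__)
    out = cmd_infer_io(cfg, outdir=outdir)
    post = yaml.safe_load((out / "io_posterior.yaml").read_text())
    for name in ("kon0", "K_D", "H"):
        lo, hi = post["band_16_84"][name]
        print(
            f"{name}: {post['posterior_mean'][name]:.2f} "
            f"(16-84%: {lo:.2f}-{hi:.2f})"
        )


if __name__ == "__main__":
    main()
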