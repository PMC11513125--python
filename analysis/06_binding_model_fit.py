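#!/usr/bin/env python
"""Fit the equilibrium cooperative-binding model (N sites, per-site k_d,
pairwise cooperativity omega) to the posterior-mean burst-frequency
response from 05_io_parameter_mcmc.py."""

import yaml

from _common import parse

from optoburst.cli import cmd_fit_binding


def main():
    cfg, outdir = parse(__doc__)
    out = cmd_fit_binding(cfg, outdir=outdir)
    fit = yaml.safe_load((out / "binding_fit.yaml").read_text())
    print(
        f"binding model: N = {fit['N']}, k_d = {fit['k_d_au']:.2f} au, "
        f"omega = {fit['omega']:.2f}, "
        f"effective Hill = {fit['effective_hill']:.2f}"
    )


if __name__ == "__main__":
    main()
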