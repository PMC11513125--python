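#!/usr/bin/env python
"""Generate the synthetic trace set: three illumination conditions plus
the repressor-export experiment, with a ground-truth ledger."""

from _common import parse

from optoburst.cli import cmd_simulate


def main():
    cfg, outdir = parse(__doc__)
    out = cmd_simulate(cfg, outdir=outdir)
    print(f"wrote traces and ground truth under {out}")


if __name__ == "__main__":
    main()
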