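# Run configuration for the numbered analysis scripts.
# Every key is optional; omitted keys fall back to the package defaults
# (see `optoburst.cli._SCHEMA` or docs/methods.md for the full list).

seed: 1
outdir: results/run

simulation:
  n_nuclei: 60        # nuclei per condition

analysis:
  n_boot: 200         # cluster-bootstrap replicates for curve SEs

io_mcmc:
  n_samples: 2400
  prior_kon0: [1.0, 8.0]
  prior_K_D: [1.5, 9.0]
  prior_H: [2.0, 14.0]
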