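# optoburst

Quantitative dissection of repressor-controlled transcriptional bursting
from paired repressor/MS2 live-imaging traces.

A transcription factor gradient can shut a gene off by making
transcriptional bursts rarer, shorter, or dimmer. `optoburst` implements
the full analysis chain needed to tell these apart from dual-color
live-imaging data (a nuclear repressor concentration and an MS2
transcription reporter per nucleus over time), together with a
generative simulator for validating every estimator against known ground
truth:

- **`synthetic_data`** — two-state (telegraph) promoter simulation driven
  by time-varying repressor concentrations, an elongation-window MS2
  signal model, repressor rise/export/recovery protocols, and full
  trace-set generation with a ground-truth ledger.
- **`trace_analysis`** — binned input-output curves with cluster
  (nucleus-level) bootstrap SEs, Hill fitting, fraction-active
  timecourses, reactivation-time extraction with censoring, a
  memorylessness regression, and exponential kinetics fits.
- **`cphmm`** — compound-state hidden Markov model burst inference: the
  hidden state is the last `w` promoter states (128 compound states at
  the defaults), EM exploits the sparse two-predecessor structure, and
  grouped inference with a segment bootstrap compares low- vs
  high-repressor regimes.
- **`io_inference`** — simulation-based inference of the microscopic
  burst-frequency response `k_on(c) = kon0 / (1 + (c/K_D)^H)`: forward
  ensembles with common random numbers, a Gaussian fit score against the
  observed curve and reactivation CDF, and log-space MCMC with
  convergence diagnostics.
- **`theory_models`** — equilibrium cooperative-binding occupancy model
  (exact log-space partition sum), the linear occupancy-repression rule,
  and closed-form noise comparisons of frequency- vs duration-modulation
  repression strategies.
- **`cli`** — `optoburst simulate | analyze | infer-bursts | infer-io |
  fit-binding`, driven by a schema-validated YAML configuration.

See `docs/methods.md` for models, estimators and numerical choices.

## Worked example

```python
import numpy as np
from optoburst import (TimeGrid, TraceSetConfig, gen_trace_set,
                       cphmm_em_infer)
from optoburst import trace_analysis as ta
from optoburst.synthetic_data import simulate_discrete_traces

grid = TimeGrid()          # 20 s frames, 35 min, 140 s elongation window

# 1. generate a synthetic trace set (3 illumination conditions + export)
df, truth = gen_trace_set(TraceSetConfig(), n_nuclei=60, seed=11)

# 2. binned input-output curve and Hill fit on unperturbed nuclei
unpert = df[~np.isfinite(df["t_perturb_sec"])]
curve = ta.compute_io_curve(unpert, n_boot=200, seed=5)
fit = ta.fit_hill(curve)
print(f"H = {fit.H:.2f} +/- {fit.se['H']:.2f}")   # H = 5.42 +/- 0.37

# 3. burst parameters by compound-HMM EM on two-state traces
ms2, _ = simulate_discrete_traces(2.3, 2.0, 2.0, 0.3, 100, 45, grid, seed=2)
res = cphmm_em_infer(ms2, grid, n_starts=2, seed=1)
print(f"k_on = {res.params.k_on:.2f}/min")        # k_on = 2.35/min (truth 2.3)
```

The empirical Hill fit (H ≈ 5.4) underestimates the generative
microscopic coefficient (H = 6.1) because the elongation window and
measurement noise smear the binned curve; the simulation-based MCMC
(`optoburst infer-io`, step 05 below) models both and recovers
`kon0 = 2.95 ± 0.35 /min`, `K_D = 3.64 ± 0.36 au`, `H = 5.7 ± 1.4`
(truths 2.8, 3.7, 6.1) on the same data.

## Repository layout

```
src/optoburst/      package modules
analysis/           numbered pipeline scripts + config.yaml
scripts/            acceptance benchmark
tests/              pytest suite (unit, property and acceptance tests)
docs/methods.md     models, estimators, numerical choices, limitations
```
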