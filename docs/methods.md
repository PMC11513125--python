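# Methods

This document describes the models, estimators and numerical choices
implemented in `optoburst`. Units throughout: time in minutes for rates
and durations (the observation grid is specified in seconds),
concentrations and fluorescence in arbitrary units (au).

## 1. Generative model

### 1.1 Two-state promoter (telegraph) model

The promoter switches between OFF and ON with concentration-dependent
rates. In the ON state, polymerases initiate at rate `r` (au of signal
per minute after calibration). The repressor concentration `c(t)`
controls the switching rates through two response functions:

- **Burst frequency** (`HillResponse`):
  `k_on(c) = kon0 / (1 + (c / K_D)^H)`, implemented in log space via the
  logistic function for overflow safety at large `H`.
  Defaults: `kon0 = 2.8 /min`, `K_D = 3.7 au`, `H = 6.1`.
- **Burst duration** (`DurationResponse`): a decreasing Hill function
  with a floor, `k_off(c) = koff_floor + (koff_base - koff_floor) /
  (1 + (c / K_D_off)^H_off)`. Defaults `koff_base = 2.0`,
  `koff_floor = 1.54 /min`, so the mean burst duration (`1/k_off`)
  increases by 30% from the low- to the high-repressor regime.

Paths are simulated on a fine grid (`dt_fine = 2 s` by default) as a
Bernoulli chain with per-step switching probabilities
`p = 1 - exp(-k dt_fine)`; a guard warns when `max(rate) * dt_fine > 0.5`.
Initial states are drawn from the instantaneous stationary distribution
`k_on / (k_on + k_off)` unless a perturbation protocol dictates OFF.

### 1.2 Elongation window and MS2 signal

An initiated polymerase stays visible for the elongation time
`w * dt` (7 frames x 20 s = 140 s by default). The noiseless frame
signal is `r * dt_min * sum of the ON occupancies of the last w frames`
(boxcar kernel; a triangular `ramp_kernel` is available for partial-
elongation weighting). A fully active promoter therefore plateaus at
`r * dt_min * w` (4.67 au at defaults). Additive Gaussian measurement
noise (sd 0.3 au) is applied and the signal clipped at zero.

### 1.3 Repressor trajectories

Each nucleus's repressor concentration follows a logistic rise to a
plateau (`c_max` scaled per illumination condition: 1.0 / 0.6 / 0.3 for
no light / low / high), with a per-nucleus multiplicative plateau factor
(CV 0.15) and additive observation noise (sd 0.3 au, truncated at zero).
The export perturbation decays exponentially (half-time 10 s) toward a
residual floor (0.5 au); recovery relaxes back with half-time 60 s.
The default trace set holds three illumination conditions plus an
export-step condition, `n_embryos` embryo labels for cluster bootstraps,
and a ground-truth ledger (true parameters, per-nucleus plateau factors
and promoter paths).

## 2. Trace analysis

- **Input-output curve**: frames of all unperturbed nuclei inside the
  anterior-posterior window are pooled and binned by observed repressor
  concentration (0.5 au bins, bins with < 50 frames suppressed). Errors
  are nucleus-level (cluster) bootstrap SEs: nuclei, not frames, are
  resampled, because frames within a nucleus are strongly correlated.
- **Hill fit**: weighted least squares with multi-start optimization
  over log-spaced midpoints; parameter SEs from the local curvature;
  flat curves are flagged rather than fitted.
- **Reactivation**: a nucleus qualifies if it is continuously below the
  detection threshold for at least 2 min before the export perturbation;
  its response time is the time to the first suprathreshold frame after
  it. Never-reactivating nuclei are kept as censored records and enter
  the CDF denominator, so the empirical CDF plateaus below 1.
- **Memorylessness**: OLS of response time on prior silent duration with
  an F-test of the slope. Under memoryless (exponential) reactivation
  the p-value is uniform; calibration was verified over 1000 simulated
  null datasets.

## 3. Compound-state HMM (cpHMM)

Because the observed signal sums the last `w` promoter states, the
hidden state is the full `w`-step history: `2^w` compound states (128 at
`w = 7`). Each state has exactly two predecessors (shift the history and
append 0 or 1), so the forward-backward and Viterbi recursions use the
sparse predecessor structure directly instead of the dense
`2^w x 2^w` transition matrix; the E-step is O(T * 2^w).

Emissions are Gaussian with mean `r * dt_min * (number of ON bits)` and
a shared sd. EM updates `(p_on, p_off, r, sigma)` with rates recovered
as `k = -ln(1 - p) / dt`. Numerical details:

- A one-predecessor subtlety: for `w >= 2` both predecessors of a state
  share the same "previous newest bit", so the incoming transition
  probability factors per state; at `w = 1` the two predecessors differ
  and must carry separate transition probabilities. The implementation
  handles both; a monotone log-likelihood guard raises if EM ever
  decreases the objective.
- `sigma` is floored at 1e-3 to avoid degenerate likelihood spikes.
- The `w = 1` special case was cross-validated against an independent
  dense textbook 2-state Gaussian HMM EM implementation (agreement to
  4 significant figures in all parameters).

**Grouped inference**: traces are cut into 15-min segments, segments are
assigned to the low group (mean repressor <= 4 au) or high group
(>= 6 au) with a deliberate gap, groups below a minimum frame count are
skipped with a warning, and uncertainty comes from a segment-level
bootstrap (refitting on resampled segments).

## 4. Simulation-based input-output inference

The microscopic parameters `(kon0, K_D, H)` are not identifiable from
the binned curve alone (the elongation window and measurement noise
distort it), so they are inferred by forward simulation:

1. **Ensembles**: per condition, 100 observed repressor trajectories are
   resampled; the raw observed series is kept for binning the predicted
   curve (so the prediction carries the same measurement noise as the
   observation) and a 3-frame moving average approximates the underlying
   driving concentration for the rate evaluation.
2. **Forward prediction**: candidate responses drive telegraph paths
   along the smoothed trajectories; simulated MS2 signals (with
   measurement noise) are binned against the raw observed concentrations
   into the same bins as the observed curve, and the reactivation CDF is
   computed from the export ensemble with the same thresholding rules.
3. **Fit score**: Gaussian log-score, `-0.5 * mean(z^2)` per observable
   block (curve bins; CDF grid points), blocks weighted equally. The
   prediction is itself a finite Monte-Carlo estimate, so predicted SEs
   are combined with the observed ones in quadrature: per-bin cluster
   (Taylor-linearized ratio-estimator) SEs for the curve, Laplace-
   smoothed binomial SEs for the CDF. Without the quadrature term the
   score at the true parameters is dominated by Monte-Carlo noise at
   bins whose observed SE is tiny.
4. **Sampling**: a coarse log-spaced sweep seeds a log-space random-walk
   Metropolis-Hastings sampler (3 chains, 20% burn-in, step-size
   adaptation toward 30% acceptance during burn-in only). Every score
   evaluation reuses the same simulation seed (common random numbers),
   making the stochastic objective a deterministic function of the
   parameters. Convergence is monitored with the Gelman-Rubin statistic;
   summaries are posterior means/sds, 16-84% bands and the 25
   best-scoring realizations.

**Reactivation kinetics** (`predict_reactivation_kinetics`) reports the
time for the mean `k_on` to recover to half its post-export steady
state, the median first-passage time from OFF (analytically
`ln 2 / k_on` for a constant post-export rate), and optionally a
detection-adjusted median from simulated fluorescence.

## 5. Equilibrium binding model

Occupancy of `N = 10` identical sites with per-site dissociation
constant `k_d` and a pairwise cooperativity `omega` applied once per
bound pair: configuration weight
`C(N, k) (c / k_d)^k omega^(k(k-1)/2)`, evaluated in log space
(`logsumexp`) for overflow safety. The repression rule is linear in
occupancy: `k_on(c) = kon0 (1 - n_b(c) / N)`. `(k_d, omega)` are fitted
to the posterior-mean burst-frequency response by least squares; the
effective Hill coefficient is the log-odds slope of fractional occupancy
at its midpoint (bounded by `N`). Note that pairwise cooperativity acts
on all `k(k-1)/2` pairs, so the transition midpoint shifts to roughly
`k_d * omega^-((N-1)/2)`; modest `omega` already produces sharp,
strongly shifted curves.

Closed-form noise predictions for the accumulated output over a time
window compare repression strategies at matched mean: the variance is
the Poisson (shot) term plus the integrated exponential autocovariance
of the promoter state, `2 r^2 p (1-p) (T/lambda - (1 - e^(-lambda T)) /
lambda^2)` with `lambda = k_on + k_off`. Lowering `k_on` (frequency
modulation) slows switching and yields a noisier output than raising
`k_off` (duration modulation) at the same mean.

## 6. Known limitations

- **Collapse is exact only for stationary input.** The elongation
  window mixes ~140 s of rate history into each frame, so during fast
  concentration changes the binned mean at a given instantaneous
  concentration depends on the trajectory shape, and input-output
  curves from different illumination conditions deviate by up to
  ~0.8 au in transition bins. The collapse test therefore uses
  constant-concentration ensembles, where the property is a theorem of
  the model.
- The discrete-time Bernoulli chain has stationary ON fraction
  `p_on / (p_on + p_off)` with `p = 1 - exp(-k dt)`, which approaches
  `k_on / (k_on + k_off)` only as `dt -> 0`; at the 20 s observation
  grid the difference is a few percent and is accounted for wherever
  exact expectations are asserted.
- The F-test in the memorylessness regression assumes Gaussian errors;
  with exponential response times at n = 60 its p-values are uniform to
  within KS detectability at 1000 replicates, but very small samples
  may be miscalibrated.
- Bootstrap SEs use the nucleus (or segment) as the resampling unit;
  embryo-level correlations beyond the nucleus are not modeled.
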