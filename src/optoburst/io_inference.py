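"""Simulation-based inference of the burst-frequency input-output function.

The microscopic parameters (maximum burst frequency ``kon0``, midpoint
``K_D``, sharpness ``H``) linking repressor concentration to burst
frequency are inferred by forward simulation: sampled repressor
trajectories from every illumination condition are pushed through the
candidate response functions, ensembles of MS2 traces are simulated, and
the predicted input-output curve and reactivation CDF are compared to the
observed ones through a Gaussian fit score. Parameter sweeps seed a
log-space random-walk Metropolis-Hastings sampler; every likelihood
evaluation reuses the same simulation random numbers (common random
numbers), making the stochastic objective a deterministic function of the
parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from ._kernels import telegraph_paths
from .responses import HillResponse, DurationResponse, kon_response, koff_response
from .synthetic_data import TimeGrid, fluorescence_from_occupancy, upsample_step
from .trace_analysis import InputOutputCurve

__all__ = [
    "HillResponse",
    "DurationResponse",
    "kon_response",
    "ForwardEnsembles",
    "ensembles_from_traces",
    "forward_predict",
    "fit_score",
    "mcmc_sample",
    "sweep_scores",
    "predict_reactivation_kinetics",
    "McmcResult",
]


@dataclass
class ForwardEnsembles:
    """Sampled repressor trajectories driving the forward model.

    ``illumination`` maps condition name to an (n, T) array of observed
    concentrations on the observation grid (used to bin the predicted
    input-output curve, so the prediction carries the same measurement
    noise as the observation); ``illumination_drive`` holds the smoothed
    versions used to evaluate the switching rates. ``export`` /
    ``export_drive`` hold the export-step ensemble with its perturbation
    time.
    """

    grid: TimeGrid
    illumination: dict[str, np.ndarray]
    illumination_drive: dict[str, np.ndarray]
    export: Optional[np.ndarray] = None
    export_drive: Optional[np.ndarray] = None
    t_perturb_sec: float = np.nan
    ms2_noise_sd: float = 0.3
    detection_threshold: float = 0.6
    dt_fine: float = 2.0


def ensembles_from_traces(
    traces: pd.DataFrame,
    grid: TimeGrid,
    n_per_condition: int = 100,
    seed: int = 0,
    ms2_noise_sd: float = 0.3,
    detection_threshold: float = 0.6,
    dt_fine: float = 2.0,
    smooth_frames: int = 3,
) -> ForwardEnsembles:
    """Sample single-nucleus repressor trajectories from a trace set.

    Sampling is with replacement, ``n_per_condition`` per condition. A
    lightly smoothed copy (moving average over ``smooth_frames`` frames)
    approximates the underlying driving concentration; the raw observed
    trajectories are kept for binning the predicted curve.
    """
    rng = np.random.default_rng(seed)
    illum: dict[str, np.ndarray] = {}
    drive: dict[str, np.ndarray] = {}
    export = export_drive = None
    tp = np.nan
    kern = np.ones(smooth_frames) / smooth_frames
    for cond, g in traces.groupby("condition"):
        wide = g.pivot_table(
            index="nucleus_id", columns="t_sec", values="knirps_au", sort=True
        )
        arr = wide.to_numpy(float)
        smooth = np.apply_along_axis(
            lambda v: np.convolve(v, kern, mode="same"), 1, arr
        )
        pick = rng.integers(0, arr.shape[0], size=n_per_condition)
        tps = g["t_perturb_sec"].dropna()
        if len(tps) > 0:
            export = arr[pick]
            export_drive = smooth[pick]
            tp = float(tps.iloc[0])
        else:
            illum[cond] = arr[pick]
            drive[cond] = smooth[pick]
    if not illum:
        raise ValueError("trace set contains no unperturbed conditions")
    return ForwardEnsembles(
        grid=grid,
        illumination=illum,
        illumination_drive=drive,
        export=export,
        export_drive=export_drive,
        t_perturb_sec=tp,
        ms2_noise_sd=ms2_noise_sd,
        detection_threshold=detection_threshold,
        dt_fine=dt_fine,
    )


def _simulate_condition(
    knirps_frames: np.ndarray,
    kon_resp: HillResponse,
    koff_resp: DurationResponse,
    r: float,
    grid: TimeGrid,
    dt_fine: float,
    rng: np.random.Generator,
    initial_off: bool = False,
):
    """Simulate paths and frame occupancies for one trajectory ensemble."""
    n, T = knirps_frames.shape
    ratio = int(round(grid.dt / dt_fine))
    fine = np.repeat(knirps_frames, ratio, axis=1)
    kon = kon_response(fine, kon_resp)
    koff = koff_response(fine, koff_resp)
    if initial_off:
        s0 = np.zeros(n, dtype=np.int8)
    else:
        p0 = kon[:, 0] / (kon[:, 0] + koff[:, 0])
        s0 = (rng.random(n) < p0).astype(np.int8)
    u = rng.random((n, fine.shape[1]))
    states = telegraph_paths(kon, koff, dt_fine / 60.0, u, s0)
    occ = states.reshape(n, T, ratio).mean(axis=2)
    return occ


def forward_predict(
    kon_resp: HillResponse,
    koff_resp: DurationResponse,
    r: float,
    ensembles: ForwardEnsembles,
    seed: int,
    bin_edges: np.ndarray,
    cdf_times_min: Optional[np.ndarray] = None,
    min_silent: float = 2.0,
    conditions: Optional[list[str]] = None,
) -> dict:
    """Predicted input-output curve and reactivation CDF.

    Simulates MS2 trace ensembles (with measurement noise) from the
    candidate response functions along the smoothed driving
    trajectories, then computes the same observables as the trace
    analysis: the binned mean MS2 signal vs the raw observed repressor
    concentration, and the detection-thresholded reactivation CDF. Both
    observables carry Monte-Carlo standard errors (cluster SE across
    forward traces for the curve; binomial SE for the CDF).
    Deterministic given ``seed``.
    """
    grid = ensembles.grid
    n_total = sum(a.shape[0] for a in ensembles.illumination.values())
    if n_total < 50:
        warnings.warn("fewer than 50 forward traces: noisy objective", RuntimeWarning)
    rng = np.random.default_rng(seed)
    c_all = []
    y_all = []
    trace_all = []
    offset = 0
    names = conditions or sorted(ensembles.illumination)
    for cond in names:
        kn_obs = ensembles.illumination[cond]
        kn_drive = ensembles.illumination_drive[cond]
        occ = _simulate_condition(
            kn_drive, kon_resp, koff_resp, r, grid, ensembles.dt_fine, rng
        )
        sig = fluorescence_from_occupancy(occ, r, grid)
        ms2 = np.clip(
            sig + rng.normal(0.0, ensembles.ms2_noise_sd, size=sig.shape), 0, None
        )
        c_all.append(kn_obs.ravel())
        y_all.append(ms2.ravel())
        n, T = kn_obs.shape
        trace_all.append(np.repeat(np.arange(offset, offset + n), T))
        offset += n
    c = np.concatenate(c_all)
    y = np.concatenate(y_all)
    tid = np.concatenate(trace_all)
    idx = np.clip(np.digitize(c, bin_edges) - 1, 0, len(bin_edges) - 2)
    inside = (c >= bin_edges[0]) & (c <= bin_edges[-1])
    n_bins = len(bin_edges) - 1
    counts = np.bincount(idx[inside], minlength=n_bins).astype(float)
    sums = np.bincount(idx[inside], weights=y[inside], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = sums / counts
    # cluster (per forward trace) standard error of each bin mean:
    # Taylor-linearised SE of the ratio estimator sum(y) / count
    comb = tid[inside] * n_bins + idx[inside]
    size = offset * n_bins
    cnt_tb = np.bincount(comb, minlength=size).reshape(offset, n_bins)
    sum_tb = np.bincount(comb, weights=y[inside], minlength=size).reshape(
        offset, n_bins
    )
    se = np.full(n_bins, np.nan)
    with np.errstate(invalid="ignore"):
        for b in range(n_bins):
            contrib = cnt_tb[:, b] > 0
            n_cl = int(contrib.sum())
            if n_cl >= 2 and counts[b] > 0:
                resid = sum_tb[contrib, b] - means[b] * cnt_tb[contrib, b]
                se[b] = np.sqrt(
                    n_cl / (n_cl - 1) * np.sum(resid**2)
                ) / counts[b]
    # carry nearest populated bin into empty bins so the score is total
    if np.any(counts == 0) and np.any(counts > 0):
        good = np.flatnonzero(counts > 0)
        for b in np.flatnonzero(counts == 0):
            src = good[np.argmin(np.abs(good - b))]
            means[b] = means[src]
            se[b] = se[src]
    centers = (bin_edges[:-1] + bin_edges[1:]) / 2
    io = InputOutputCurve(
        bin_centers=centers,
        mean_rate=means,
        se=se,
        n_points=counts,
        bin_width=float(bin_edges[1] - bin_edges[0]),
    )

    cdf = cdf_se = None
    if ensembles.export is not None and cdf_times_min is not None:
        occ = _simulate_condition(
            ensembles.export_drive, kon_resp, koff_resp, r, grid,
            ensembles.dt_fine, rng,
        )
        sig = fluorescence_from_occupancy(occ, r, grid)
        ms2 = np.clip(
            sig + rng.normal(0.0, ensembles.ms2_noise_sd, size=sig.shape), 0, None
        )
        cdf, cdf_se = _reactivation_cdf_arrays(
            ms2,
            grid.times,
            ensembles.t_perturb_sec,
            ensembles.detection_threshold,
            min_silent,
            np.asarray(cdf_times_min, dtype=float),
        )
    return {"io_curve": io, "cdf": cdf, "cdf_se": cdf_se}


def _reactivation_cdf_arrays(
    ms2: np.ndarray,
    t_sec: np.ndarray,
    t_perturb_sec: float,
    threshold: float,
    min_silent: float,
    cdf_times_min: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised reactivation CDF and its binomial SE over an (n, T) array.

    The SE uses the Laplace-smoothed success fraction, so it stays
    strictly positive at saturated grid points.
    """
    pre = t_sec < t_perturb_sec
    post = t_sec >= t_perturb_sec
    if not post.any():
        raise ValueError("perturbation time lies outside the time grid")
    active = ms2 >= threshold
    t_pre = t_sec[pre]
    act_pre = active[:, pre]
    # time of last pre-perturbation activity (or movie start)
    last = np.where(
        act_pre.any(axis=1),
        t_pre[act_pre.shape[1] - 1 - np.argmax(act_pre[:, ::-1], axis=1)],
        t_sec[0],
    )
    silent_min = (t_perturb_sec - last) / 60.0
    qualify = silent_min >= min_silent
    act_post = active[:, post]
    t_post = t_sec[post]
    has = act_post.any(axis=1)
    first = np.where(has, t_post[np.argmax(act_post, axis=1)], np.inf)
    resp_min = (first - t_perturb_sec) / 60.0
    resp = resp_min[qualify]
    n_total = max(resp.size, 1)
    finite = np.sort(resp[np.isfinite(resp)])
    k = np.searchsorted(finite, cdf_times_min, side="right")
    q_smooth = (k + 1) / (n_total + 2)
    se = np.sqrt(q_smooth * (1 - q_smooth) / n_total)
    return k / n_total, se


def fit_score(predicted: dict, observed: dict, se_floor: float = 1e-6) -> float:
    """Gaussian log-score of a forward prediction against observations.

    ``observed`` holds ``io_curve`` (an :class:`InputOutputCurve` with
    bootstrap SEs) and optionally ``cdf`` / ``cdf_se`` arrays on the same
    grid as the prediction. The forward prediction is itself a finite
    Monte-Carlo estimate, so when it carries SEs they are combined with
    the observed ones in quadrature; this keeps the score finite at
    grid points where the observed bootstrap SE collapses to zero (e.g.
    a saturated CDF). Each observable block is weighted by the inverse
    of its number of points, so the curve and the CDF contribute equally
    in expectation. The maximum attainable score is 0.
    """
    obs_io: InputOutputCurve = observed["io_curve"]
    se = np.asarray(obs_io.se, dtype=float)
    if np.any(~np.isfinite(se)):
        raise ValueError("observed input-output curve must carry SEs")
    pred_io: InputOutputCurve = predicted["io_curve"]
    if pred_io.bin_centers.size != obs_io.bin_centers.size:
        raise ValueError("predicted and observed curves use different bins")
    pred_se = np.asarray(pred_io.se, dtype=float)
    se = np.sqrt(se**2 + np.where(np.isfinite(pred_se), pred_se, 0.0) ** 2)
    se = np.clip(se, se_floor, None)
    z_io = (pred_io.mean_rate - obs_io.mean_rate) / se
    score = -0.5 * float(np.mean(z_io**2))
    if observed.get("cdf") is not None:
        if predicted.get("cdf") is None:
            raise ValueError("observation includes a CDF but prediction does not")
        cdf_se = np.asarray(observed["cdf_se"], dtype=float)
        if np.any(~np.isfinite(cdf_se)):
            raise ValueError("observed CDF must carry SEs")
        pred_cdf_se = predicted.get("cdf_se")
        if pred_cdf_se is not None:
            cdf_se = np.sqrt(cdf_se**2 + np.asarray(pred_cdf_se, dtype=float) ** 2)
        cdf_se = np.clip(cdf_se, se_floor, None)
        z_cdf = (np.asarray(predicted["cdf"]) - np.asarray(observed["cdf"])) / cdf_se
        score += -0.5 * float(np.mean(z_cdf**2))
    return score


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

@dataclass
class McmcResult:
    param_names: list[str]
    chains: np.ndarray          # (n_chains, n_steps, d), natural scale
    log_scores: np.ndarray      # (n_chains, n_steps)
    acceptance_rate: float
    burn_in: int
    samples: np.ndarray = None  # pooled post-burn-in draws (m, d)
    posterior_mean: dict = field(default_factory=dict)
    posterior_sd: dict = field(default_factory=dict)
    best: pd.DataFrame = None   # 25 best-fitting realizations
    rhat: dict = field(default_factory=dict)

    def quantile_band(self, lo: float = 0.16, hi: float = 0.84) -> dict:
        """Per-parameter sample quantiles ("1 sigma" band at defaults)."""
        out = {}
        for j, name in enumerate(self.param_names):
            out[name] = (
                float(np.quantile(self.samples[:, j], lo)),
                float(np.quantile(self.samples[:, j], hi)),
            )
        return out


def _gelman_rubin(chains: np.ndarray) -> np.ndarray:
    """Split-free potential scale reduction factor per parameter."""
    m, n, d = chains.shape
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean(axis=0)
    B = n * means.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.sqrt(var_hat / W)


def mcmc_sample(
    score_fn: Callable[[np.ndarray], float],
    priors: dict[str, tuple[float, float]],
    n_samples: int = 2000,
    n_chains: int = 3,
    step_scales: Optional[np.ndarray] = None,
    seed: int = 0,
    burn_in_frac: float = 0.2,
    init: Optional[np.ndarray] = None,
    adapt: bool = True,
) -> McmcResult:
    """Random-walk Metropolis-Hastings on log-transformed parameters.

    ``priors`` maps parameter name to (lo, hi) bounds of a log-uniform
    prior. ``score_fn`` receives a parameter vector on the natural scale
    and must be deterministic (use common random numbers for stochastic
    objectives). Step sizes adapt toward ~30% acceptance during burn-in
    and are then frozen. Posterior summaries pool post-burn-in samples
    from all chains; ``best`` holds the 25 highest-scoring realizations.
    """
    names = list(priors)
    d = len(names)
    lo = np.log([priors[k][0] for k in names])
    hi = np.log([priors[k][1] for k in names])
    if np.any(hi <= lo):
        raise ValueError("prior bounds must satisfy lo < hi")
    if n_samples < 1000:
        warnings.warn(
            "n_samples < 1000 is below the recommended minimum", RuntimeWarning
        )
    steps = (
        np.full(d, 0.08)
        if step_scales is None
        else np.asarray(step_scales, dtype=float)
    )
    n_per = int(np.ceil(n_samples / n_chains))
    burn = int(burn_in_frac * n_per)
    rng = np.random.default_rng(seed)
    chains = np.empty((n_chains, n_per, d))
    scores = np.empty((n_chains, n_per))
    n_acc = 0
    n_prop = 0
    for ci in range(n_chains):
        step = steps.copy()
        if init is None:
            x = lo + rng.random(d) * (hi - lo)
        else:
            x = np.log(np.asarray(init, dtype=float)) + rng.normal(0, 0.05, d)
            x = np.clip(x, lo, hi)
        s = score_fn(np.exp(x))
        acc_win = 0
        for t in range(n_per):
            prop = x + rng.normal(0.0, step)
            n_prop += 1
            if np.all(prop >= lo) & np.all(prop <= hi):
                sp = score_fn(np.exp(prop))
                if np.log(rng.random()) < sp - s:
                    x, s = prop, sp
                    n_acc += 1
                    acc_win += 1
            chains[ci, t] = np.exp(x)
            scores[ci, t] = s
            if adapt and t < burn and (t + 1) % 50 == 0:
                rate = acc_win / 50
                step *= np.exp(0.5 * (rate - 0.3))
                acc_win = 0
    acc_rate = n_acc / max(n_prop, 1)
    if not 0.05 < acc_rate < 0.7:
        warnings.warn(
            f"MCMC acceptance rate {acc_rate:.2f} outside (0.05, 0.7)",
            RuntimeWarning,
        )
    post = chains[:, burn:, :]
    samples = post.reshape(-1, d)
    flat_scores = scores[:, burn:].ravel()
    order = np.argsort(scores.ravel())[::-1][:25]
    best = pd.DataFrame(
        chains.reshape(-1, d)[order], columns=names
    ).assign(log_score=scores.ravel()[order])
    rhat = _gelman_rubin(post)
    if np.any(rhat > 1.2):
        warnings.warn(
            f"Gelman-Rubin statistic above 1.2: {dict(zip(names, rhat))}",
            RuntimeWarning,
        )
    return McmcResult(
        param_names=names,
        chains=chains,
        log_scores=scores,
        acceptance_rate=float(acc_rate),
        burn_in=burn,
        samples=samples,
        posterior_mean={k: float(samples[:, j].mean()) for j, k in enumerate(names)},
        posterior_sd={k: float(samples[:, j].std(ddof=1)) for j, k in enumerate(names)},
        best=best,
        rhat={k: float(rhat[j]) for j, k in enumerate(names)},
    )


def sweep_scores(
    score_fn: Callable[[np.ndarray], float],
    grids: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Coarse full-factorial parameter sweep; returns scores sorted best-first."""
    names = list(grids)
    mesh = np.meshgrid(*[grids[k] for k in names], indexing="ij")
    points = np.stack([m.ravel() for m in mesh], axis=1)
    rows = [
        dict(zip(names, p)) | {"log_score": score_fn(p)} for p in points
    ]
    return pd.DataFrame(rows).sort_values("log_score", ascending=False).reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# reactivation kinetics
# ---------------------------------------------------------------------------

def predict_reactivation_kinetics(
    kon_resp: HillResponse,
    export_trajectories: np.ndarray,
    grid: TimeGrid,
    t_perturb_sec: float,
    seed: int,
    koff_resp: Optional[DurationResponse] = None,
    r: float = 2.0,
    detection_threshold: Optional[float] = None,
    ms2_noise_sd: float = 0.0,
    dt_fine: float = 2.0,
) -> dict:
    """Reactivation time scales implied by the burst-frequency response.

    Returns the time for the mean ``k_on`` to recover to half its
    post-export steady-state value, the median first-passage time from
    OFF into the ON state after the perturbation, and (when a detection
    threshold is given) the detection-adjusted median: the time for the
    simulated fluorescence to first cross the threshold.
    """
    if not np.isfinite(t_perturb_sec):
        raise ValueError("export trajectories must carry a perturbation time")
    export_trajectories = np.atleast_2d(np.asarray(export_trajectories, dtype=float))
    t = grid.times
    post = t >= t_perturb_sec
    mean_c = export_trajectories.mean(axis=0)
    kon_t = np.atleast_1d(kon_response(mean_c, kon_resp))
    kon_ss = kon_t[post][-1]
    half = kon_ss / 2.0
    above = post & (kon_t >= half)
    t_half_recovery = (
        float(t[above][0] - t_perturb_sec) if above.any() else np.nan
    )

    # first passage from OFF, simulated on the fine grid post-perturbation
    rng = np.random.default_rng(seed)
    ratio = int(round(grid.dt / dt_fine))
    fine_c = np.repeat(export_trajectories[:, post], ratio, axis=1)
    kon_fine = kon_response(fine_c, kon_resp)
    n, Tf = kon_fine.shape
    u = rng.random((n, Tf))
    p = 1.0 - np.exp(-kon_fine * dt_fine / 60.0)
    hit = u < p
    has = hit.any(axis=1)
    first_idx = np.argmax(hit, axis=1)
    fp_sec = np.where(has, (first_idx + 1) * dt_fine, np.inf)
    median_fp_sec = float(np.median(fp_sec))

    out = {
        "kon_half_recovery_sec": t_half_recovery,
        "median_first_passage_sec": median_fp_sec,
        "median_first_passage_min": median_fp_sec / 60.0,
    }
    if detection_threshold is not None:
        if koff_resp is None:
            raise ValueError("detection-adjusted estimate needs a duration response")
        occ = _simulate_condition(
            export_trajectories[:, post],
            kon_resp,
            koff_resp,
            r,
            grid,
            dt_fine,
            rng,
            initial_off=True,
        )
        sig = fluorescence_from_occupancy(occ, r, grid)
        if ms2_noise_sd > 0:
            sig = np.clip(
                sig + rng.normal(0.0, ms2_noise_sd, size=sig.shape), 0, None
            )
        cross = sig >= detection_threshold
        has = cross.any(axis=1)
        idx = np.argmax(cross, axis=1)
        t_det = np.where(has, idx * grid.dt, np.inf)
        out["median_detection_adjusted_sec"] = float(np.median(t_det))
    return out
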