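"""Compound-state hidden Markov model for burst-parameter inference.

MS2 fluorescence integrates promoter activity over the elongation time
(``w`` sampling steps), so the observable at frame ``t`` depends on the
promoter's last ``w`` states. The hidden state of the HMM is therefore the
full length-``w`` binary history (2**w compound states; 128 at the default
``w = 7``). Transitions append the new promoter state and drop the oldest;
the emission is Gaussian with mean ``r * dt * (number of ON steps in the
history)`` under the uniform elongation kernel.

Expectation-maximization over this chain recovers the telegraph-model
parameters: burst frequency ``k_on``, burst termination rate ``k_off``
(burst duration ``1/k_off``), initiation rate ``r`` (burst amplitude) and
the emission noise scale. Discrete-time switching probabilities are
converted back to continuous-time rates via ``k = -ln(1 - p) / dt``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .synthetic_data import TimeGrid

__all__ = [
    "BurstParams",
    "CompoundModel",
    "build_compound_model",
    "cphmm_em_infer",
    "grouped_bootstrap_inference",
    "CpHmmResult",
]

_MAX_W = 12  # 4096 states; beyond this the state space explodes


@dataclass(frozen=True)
class BurstParams:
    """Telegraph-model parameter triple plus emission noise scale.

    Burst frequency = ``k_on``; burst duration = ``1/k_off``; burst
    amplitude = ``r``.
    """

    k_on: float   # 1/min
    k_off: float  # 1/min
    r: float      # au/min
    sigma: float  # au

    def __post_init__(self) -> None:
        if not (self.k_on > 0 and self.k_off > 0 and self.r > 0 and self.sigma > 0):
            raise ValueError("all burst parameters must be positive")


@dataclass
class CompoundModel:
    """Exact history chain over the last ``w`` promoter states."""

    w: int
    dt_min: float
    p_on: float             # per-step OFF -> ON probability
    p_off: float            # per-step ON -> OFF probability
    emission_means: np.ndarray  # (2**w,), au
    sigma: float
    on_counts: np.ndarray       # kernel-weighted ON content per state

    @property
    def n_states(self) -> int:
        return 1 << self.w

    def transition_matrix(self) -> np.ndarray:
        """Dense (2**w, 2**w) transition matrix (rows sum to 1)."""
        K = self.n_states
        mask = K - 1
        A = np.zeros((K, K))
        for s in range(K):
            cur = s & 1
            succ0 = (s << 1) & mask
            succ1 = succ0 | 1
            if cur == 0:
                A[s, succ1] = self.p_on
                A[s, succ0] = 1.0 - self.p_on
            else:
                A[s, succ0] = self.p_off
                A[s, succ1] = 1.0 - self.p_off
        return A


def _state_bits(w: int) -> np.ndarray:
    """(2**w, w) matrix of history bits; column i is the state at lag i."""
    s = np.arange(1 << w)
    return (s[:, None] >> np.arange(w)[None, :]) & 1


def build_compound_model(
    params: BurstParams,
    grid: TimeGrid,
    kernel: Optional[np.ndarray] = None,
) -> CompoundModel:
    """Construct the compound chain for given burst parameters and grid."""
    if grid.w > _MAX_W:
        raise ValueError(
            f"w = {grid.w} gives {1 << grid.w} compound states; limit is "
            f"w <= {_MAX_W}"
        )
    if kernel is None:
        kernel = np.ones(grid.w)
    kernel = np.asarray(kernel, dtype=float)
    if kernel.size != grid.w:
        raise ValueError("kernel length must equal w")
    dt = grid.dt_min
    p_on = 1.0 - np.exp(-params.k_on * dt)
    p_off = 1.0 - np.exp(-params.k_off * dt)
    counts = _state_bits(grid.w).astype(float) @ kernel
    return CompoundModel(
        w=grid.w,
        dt_min=dt,
        p_on=float(p_on),
        p_off=float(p_off),
        emission_means=params.r * dt * counts,
        sigma=params.sigma,
        on_counts=counts,
    )


# ---------------------------------------------------------------------------
# forward-backward machinery (sparse in the history structure)
# ---------------------------------------------------------------------------

def _structure(w: int):
    K = 1 << w
    mask = K - 1
    s = np.arange(K)
    pred0 = s >> 1                      # predecessors of each state
    pred1 = pred0 | (1 << (w - 1))
    succ0 = (s << 1) & mask             # successors of each state
    succ1 = succ0 | 1
    bit0 = s & 1                        # newest promoter state
    bit1 = (s >> 1) & 1                 # previous promoter state
    return K, pred0, pred1, succ0, succ1, bit0, bit1


def _trans_vectors(p_on: float, p_off: float, bit_prev, bit_new):
    """Per-state transition probability given (previous bit, new bit)."""
    tp = np.where(
        bit_prev == 0,
        np.where(bit_new == 1, p_on, 1.0 - p_on),
        np.where(bit_new == 0, p_off, 1.0 - p_off),
    )
    return tp


def _e_step(y: np.ndarray, pi: np.ndarray, model: CompoundModel):
    """Batched scaled forward-backward over equal-length traces.

    Returns the total log-likelihood and the sufficient statistics
    (transition counts by (prev, new) promoter bit, gamma moments for the
    emission update, and the summed first-frame posterior).
    """
    n, T = y.shape
    w = model.w
    K, pred0, pred1, succ0, succ1, bit0, bit1 = _structure(w)
    mu = model.emission_means
    sigma = model.sigma

    logB = -0.5 * ((y[:, :, None] - mu[None, None, :]) / sigma) ** 2 - np.log(
        sigma * np.sqrt(2 * np.pi)
    )
    shift = logB.max(axis=2)
    Bh = np.exp(logB - shift[:, :, None])

    # transition probability into s' from each of its two predecessors
    # (their newest bits coincide for w >= 2, but differ at w = 1)
    tp_p0 = _trans_vectors(model.p_on, model.p_off, pred0 & 1, bit0)
    tp_p1 = _trans_vectors(model.p_on, model.p_off, pred1 & 1, bit0)

    alphas = np.empty((T, n, K))
    c = np.empty((T, n))
    a = pi[None, :] * Bh[:, 0, :]
    c[0] = a.sum(axis=1)
    alphas[0] = a / c[0][:, None]
    for t in range(1, T):
        spread = (
            alphas[t - 1][:, pred0] * tp_p0[None, :]
            + alphas[t - 1][:, pred1] * tp_p1[None, :]
        )
        a = Bh[:, t, :] * spread
        c[t] = a.sum(axis=1)
        alphas[t] = a / c[t][:, None]
    loglik = float(np.log(c).sum() + shift.sum())

    # backward pass, accumulating gamma moments and transition counts
    tp_out0 = _trans_vectors(model.p_on, model.p_off, bit0, np.zeros(K, int))
    tp_out1 = _trans_vectors(model.p_on, model.p_off, bit0, np.ones(K, int))
    off_mask = (bit0 == 0).astype(float)
    on_mask = 1.0 - off_mask

    trans = np.zeros((2, 2))  # [prev_bit, new_bit] expected counts
    g_my = 0.0   # sum gamma * m_s * y
    g_mm = 0.0   # sum gamma * m_s**2
    g_m = np.zeros(K)  # summed gamma per state (for sigma update)
    y_sum = 0.0
    y2_sum = 0.0
    gamma_y = np.zeros(K)  # sum over n,t of gamma * y per state

    beta = np.ones((n, K))
    for t in range(T - 1, -1, -1):
        gamma = alphas[t] * beta
        gsum = gamma.sum(axis=0)
        g_m += gsum
        gy = gamma * y[:, t][:, None]
        gamma_y += gy.sum(axis=0)
        if t == 0:
            gamma0 = gamma.sum(axis=0)
        if t > 0:
            bb = Bh[:, t, :] * beta / c[t][:, None]
            v0 = alphas[t - 1] * tp_out0[None, :] * bb[:, succ0]
            v1 = alphas[t - 1] * tp_out1[None, :] * bb[:, succ1]
            trans[0, 0] += float((v0 * off_mask[None, :]).sum())
            trans[0, 1] += float((v1 * off_mask[None, :]).sum())
            trans[1, 0] += float((v0 * on_mask[None, :]).sum())
            trans[1, 1] += float((v1 * on_mask[None, :]).sum())
            beta = tp_out0[None, :] * bb[:, succ0] + tp_out1[None, :] * bb[:, succ1]

    m = model.on_counts
    g_my = float(gamma_y @ m)
    g_mm = float(g_m @ (m**2))
    stats = {
        "trans": trans,
        "g_my": g_my,
        "g_mm": g_mm,
        "g_m": g_m,
        "gamma_y": gamma_y,
        "gamma0": gamma0,
        "n_obs": n * T,
        "y2": float((y**2).sum()),
    }
    return loglik, stats, alphas, c, Bh


def _posterior_on(y: np.ndarray, pi: np.ndarray, model: CompoundModel) -> np.ndarray:
    """Per-frame posterior probability that the promoter is ON."""
    n, T = y.shape
    K, pred0, pred1, succ0, succ1, bit0, bit1 = _structure(model.w)
    mu, sigma = model.emission_means, model.sigma
    logB = -0.5 * ((y[:, :, None] - mu[None, None, :]) / sigma) ** 2
    shift = logB.max(axis=2)
    Bh = np.exp(logB - shift[:, :, None])
    tp_p0 = _trans_vectors(model.p_on, model.p_off, pred0 & 1, bit0)
    tp_p1 = _trans_vectors(model.p_on, model.p_off, pred1 & 1, bit0)
    tp_out0 = _trans_vectors(model.p_on, model.p_off, bit0, np.zeros(K, int))
    tp_out1 = _trans_vectors(model.p_on, model.p_off, bit0, np.ones(K, int))
    alphas = np.empty((T, n, K))
    c = np.empty((T, n))
    a = pi[None, :] * Bh[:, 0, :]
    c[0] = a.sum(axis=1)
    alphas[0] = a / c[0][:, None]
    for t in range(1, T):
        spread = (
            alphas[t - 1][:, pred0] * tp_p0[None, :]
            + alphas[t - 1][:, pred1] * tp_p1[None, :]
        )
        a = Bh[:, t, :] * spread
        c[t] = a.sum(axis=1)
        alphas[t] = a / c[t][:, None]
    post = np.empty((n, T))
    beta = np.ones((n, K))
    onbits = bit0.astype(float)
    for t in range(T - 1, -1, -1):
        gamma = alphas[t] * beta
        post[:, t] = gamma @ onbits
        if t > 0:
            bb = Bh[:, t, :] * beta / c[t][:, None]
            beta = tp_out0[None, :] * bb[:, succ0] + tp_out1[None, :] * bb[:, succ1]
    return post


def _viterbi(y: np.ndarray, pi: np.ndarray, model: CompoundModel) -> np.ndarray:
    """Most likely current-frame promoter state sequence per trace."""
    n, T = y.shape
    K, pred0, pred1, succ0, succ1, bit0, bit1 = _structure(model.w)
    mu, sigma = model.emission_means, model.sigma
    logB = -0.5 * ((y[:, :, None] - mu[None, None, :]) / sigma) ** 2
    with np.errstate(divide="ignore"):
        log_tp_p0 = np.log(
            _trans_vectors(model.p_on, model.p_off, pred0 & 1, bit0)
        )
        log_tp_p1 = np.log(
            _trans_vectors(model.p_on, model.p_off, pred1 & 1, bit0)
        )
        log_pi = np.log(np.clip(pi, 1e-300, None))
    delta = log_pi[None, :] + logB[:, 0, :]
    back = np.empty((T, n, K), dtype=np.int8)
    for t in range(1, T):
        d0 = delta[:, pred0] + log_tp_p0[None, :]
        d1 = delta[:, pred1] + log_tp_p1[None, :]
        take1 = d1 > d0
        back[t] = take1
        delta = np.where(take1, d1, d0) + logB[:, t, :]
    states = np.empty((n, T), dtype=np.int64)
    s = delta.argmax(axis=1)
    states[:, T - 1] = s
    for t in range(T - 1, 0, -1):
        chose1 = back[t][np.arange(n), s]
        s = np.where(chose1, pred1[s], pred0[s])
        states[:, t - 1] = s
    return (states & 1).astype(np.int8)


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

@dataclass
class CpHmmResult:
    params: BurstParams
    loglik: float
    n_iter: int
    converged: bool
    flags: list = field(default_factory=list)
    loglik_trace: np.ndarray = None
    posterior_on: Optional[list] = None
    viterbi: Optional[list] = None


def _as_groups(traces) -> list[np.ndarray]:
    """Group traces by length into 2-D batches."""
    if isinstance(traces, np.ndarray) and traces.ndim == 2:
        return [np.asarray(traces, dtype=float)]
    arrs = [np.asarray(tr, dtype=float).ravel() for tr in traces]
    by_len: dict[int, list] = {}
    for a in arrs:
        by_len.setdefault(a.size, []).append(a)
    return [np.vstack(v) for v in by_len.values()]


def _moment_init(ys: list[np.ndarray], grid: TimeGrid, rng) -> BurstParams:
    y = np.concatenate([a.ravel() for a in ys])
    top = np.quantile(y, 0.975)
    r0 = max(top / (grid.dt_min * grid.w), 1e-3)
    occ = np.clip(y.mean() / max(top, 1e-9), 0.05, 0.95)
    k_off0 = float(np.exp(rng.normal(np.log(2.0), 0.5)))
    k_on0 = float(np.clip(occ / (1 - occ) * k_off0, 1e-2, 30.0))
    r0 = float(r0 * np.exp(rng.normal(0.0, 0.3)))
    sigma0 = float(max(np.std(y) * 0.5, 1e-3))
    return BurstParams(k_on=k_on0, k_off=k_off0, r=r0, sigma=sigma0)


def _stationary_pi(model: CompoundModel) -> np.ndarray:
    """Stationary distribution over histories of the two-state chain."""
    p_on, p_off = model.p_on, model.p_off
    q1 = p_on / (p_on + p_off)
    bits = _state_bits(model.w)
    # probability of the path oldest -> newest
    pi = np.where(bits[:, model.w - 1] == 1, q1, 1 - q1).astype(float)
    for i in range(model.w - 1, 0, -1):
        prev = bits[:, i]
        new = bits[:, i - 1]
        step = _trans_vectors(p_on, p_off, prev, new)
        pi = pi * step
    return pi / pi.sum()


def _run_em(
    groups: list[np.ndarray],
    grid: TimeGrid,
    init: BurstParams,
    max_iter: int,
    tol: float,
    kernel: Optional[np.ndarray],
) -> tuple[BurstParams, np.ndarray, float, int, bool, list]:
    dt = grid.dt_min
    params = init
    model = build_compound_model(params, grid, kernel)
    pi = _stationary_pi(model)
    flags: list[str] = []
    ll_trace = []
    prev_ll = -np.inf
    sigma_floor = 1e-3
    converged = False
    for it in range(max_iter):
        model = build_compound_model(params, grid, kernel)
        model.sigma = params.sigma
        total_ll = 0.0
        trans = np.zeros((2, 2))
        g_my = g_mm = 0.0
        g_m = np.zeros(model.n_states)
        gamma_y = np.zeros(model.n_states)
        gamma0 = np.zeros(model.n_states)
        n_obs = 0
        y2 = 0.0
        n_traces = 0
        for y in groups:
            ll, stats, *_ = _e_step(y, pi, model)
            total_ll += ll
            trans += stats["trans"]
            g_my += stats["g_my"]
            g_mm += stats["g_mm"]
            g_m += stats["g_m"]
            gamma_y += stats["gamma_y"]
            gamma0 += stats["gamma0"]
            n_obs += stats["n_obs"]
            y2 += stats["y2"]
            n_traces += y.shape[0]
        if total_ll < prev_ll - tol * (1 + abs(prev_ll)):
            raise RuntimeError(
                f"EM log-likelihood decreased at iteration {it}: "
                f"{prev_ll} -> {total_ll}"
            )
        ll_trace.append(total_ll)
        if it > 0 and abs(total_ll - prev_ll) < tol * (1 + abs(total_ll)):
            converged = True
            prev_ll = total_ll
            break
        prev_ll = total_ll

        # M-step
        p_on = trans[0, 1] / max(trans[0, 0] + trans[0, 1], 1e-12)
        p_off = trans[1, 0] / max(trans[1, 0] + trans[1, 1], 1e-12)
        p_on = float(np.clip(p_on, 1e-6, 1 - 1e-6))
        p_off = float(np.clip(p_off, 1e-6, 1 - 1e-6))
        m = model.on_counts
        r_new = (gamma_y @ m) / max(dt * (g_m @ (m**2)), 1e-12)
        r_new = float(max(r_new, 1e-6))
        mu_new = r_new * dt * m
        sse = y2 - 2 * r_new * dt * (gamma_y @ m) + g_m @ (mu_new**2)
        sigma_new = float(np.sqrt(max(sse, 0.0) / n_obs))
        if sigma_new < sigma_floor:
            sigma_new = sigma_floor
            if "sigma floored" not in flags:
                flags.append("sigma floored")
        pi = gamma0 / n_traces
        pi = np.clip(pi, 0.0, None)
        pi = pi / pi.sum()
        params = BurstParams(
            k_on=float(-np.log(1 - p_on) / dt),
            k_off=float(-np.log(1 - p_off) / dt),
            r=r_new,
            sigma=sigma_new,
        )
    return params, pi, prev_ll, len(ll_trace), converged, flags, np.array(ll_trace)


def cphmm_em_infer(
    traces,
    grid: TimeGrid,
    init: Optional[BurstParams] = None,
    max_iter: int = 200,
    tol: float = 1e-7,
    n_starts: int = 5,
    seed: int = 0,
    kernel: Optional[np.ndarray] = None,
    return_posterior: bool = False,
    viterbi: bool = False,
) -> CpHmmResult:
    """Infer burst parameters from MS2 traces by EM over the compound chain.

    ``traces`` is a 2-D array (n_traces, n_frames) or a sequence of 1-D
    arrays. When ``init`` is given a single EM run starts there; otherwise
    ``n_starts`` runs start from jittered moment-based guesses and the best
    log-likelihood is kept. The log-likelihood is checked to be
    non-decreasing at every iteration.
    """
    groups = _as_groups(traces)
    for g in groups:
        if g.shape[1] < 3 * grid.w:
            raise ValueError("each trace must have at least 3*w frames")
    rng = np.random.default_rng(seed)
    inits = [init] if init is not None else [
        _moment_init(groups, grid, rng) for _ in range(n_starts)
    ]
    best = None
    for ini in inits:
        params, pi, ll, n_iter, conv, flags, ll_trace = _run_em(
            groups, grid, ini, max_iter, tol, kernel
        )
        if best is None or ll > best[2]:
            best = (params, pi, ll, n_iter, conv, flags, ll_trace)
    params, pi, ll, n_iter, conv, flags, ll_trace = best
    result = CpHmmResult(
        params=params,
        loglik=ll,
        n_iter=n_iter,
        converged=conv,
        flags=list(flags),
        loglik_trace=ll_trace,
    )
    model = build_compound_model(params, grid, kernel)
    model.sigma = params.sigma
    if return_posterior:
        result.posterior_on = [_posterior_on(g, pi, model) for g in groups]
    if viterbi:
        result.viterbi = [_viterbi(g, pi, model) for g in groups]
    return result


# ---------------------------------------------------------------------------
# grouped inference with segment bootstrap
# ---------------------------------------------------------------------------

def segment_traces(
    traces: pd.DataFrame,
    grid: TimeGrid,
    segment_min: float = 15.0,
) -> pd.DataFrame:
    """Cut each nucleus's trace into consecutive non-overlapping segments of
    ``segment_min`` minutes; returns one row per segment with the MS2 frame
    array and the segment's mean repressor concentration."""
    frames_per_seg = int(round(segment_min * 60.0 / grid.dt))
    rows = []
    for nid, g in traces.groupby("nucleus_id"):
        g = g.sort_values("t_sec")
        y = g["ms2_au"].to_numpy(float)
        c = g["knirps_au"].to_numpy(float)
        n_seg = y.size // frames_per_seg
        for k in range(n_seg):
            sl = slice(k * frames_per_seg, (k + 1) * frames_per_seg)
            rows.append(
                {
                    "nucleus_id": nid,
                    "segment": k,
                    "mean_knirps": float(np.nanmean(c[sl])),
                    "ms2": np.nan_to_num(y[sl], nan=0.0),
                }
            )
    return pd.DataFrame(rows)


def grouped_bootstrap_inference(
    traces: pd.DataFrame,
    grid: TimeGrid,
    knirps_low_max: float = 4.0,
    knirps_high_min: float = 6.0,
    segment_min: float = 15.0,
    n_boot: int = 10,
    min_points: Optional[dict] = None,
    seed: int = 0,
    max_iter: int = 200,
    n_starts: int = 5,
) -> dict:
    """Burst-parameter inference for low/high repressor-concentration groups.

    Trace segments are assigned by their mean repressor concentration over
    the segment (low: <= ``knirps_low_max``; high: >= ``knirps_high_min``;
    the gap in between belongs to neither group). Each bootstrap replicate
    resamples segments with replacement until it holds at least
    ``min_points`` frames, then reruns EM initialised at the group point
    estimate; the reported SE is the SD across replicates.
    """
    if knirps_low_max >= knirps_high_min:
        raise ValueError("knirps_low_max must be < knirps_high_min")
    if min_points is None:
        min_points = {"low": 10000, "high": 6027}
    segs = segment_traces(traces, grid, segment_min)
    out = {}
    rng = np.random.default_rng(seed)
    for group, sel in (
        ("low", segs["mean_knirps"] <= knirps_low_max),
        ("high", segs["mean_knirps"] >= knirps_high_min),
    ):
        pool = segs.loc[sel, "ms2"].to_list()
        if not pool:
            warnings.warn(f"group {group!r} has no qualifying segments; skipped")
            continue
        y = np.vstack(pool)
        point = cphmm_em_infer(
            y, grid, n_starts=n_starts, max_iter=max_iter,
            seed=int(rng.integers(2**31)),
        )
        frames_per_seg = y.shape[1]
        reps = []
        for b in range(n_boot):
            n_draw = max(
                len(pool), int(np.ceil(min_points[group] / frames_per_seg))
            )
            pick = rng.integers(0, len(pool), size=n_draw)
            yb = y[pick]
            res = cphmm_em_infer(
                yb, grid, init=point.params, max_iter=max_iter,
                seed=int(rng.integers(2**31)),
            )
            reps.append(
                {
                    "k_on": res.params.k_on,
                    "k_off": res.params.k_off,
                    "r": res.params.r,
                    "sigma": res.params.sigma,
                    "duration": 1.0 / res.params.k_off,
                    "n_points": yb.size,
                }
            )
        reps = pd.DataFrame(reps)
        flagged = n_boot < 2
        if flagged:
            warnings.warn("n_boot < 2: bootstrap SE undefined")
        out[group] = {
            "point": point.params,
            "mean": reps[["k_on", "k_off", "r", "sigma", "duration"]].mean().to_dict(),
            "sd": (
                reps[["k_on", "k_off", "r", "sigma", "duration"]].std(ddof=1).to_dict()
                if not flagged
                else {k: np.nan for k in ("k_on", "k_off", "r", "sigma", "duration")}
            ),
            "replicates": reps,
            "n_segments": len(pool),
            "n_boot": n_boot,
            "flagged": flagged,
        }
    return out
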