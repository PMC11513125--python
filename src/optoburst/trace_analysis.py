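"""Descriptive and statistical analyses of paired repressor / MS2 trace sets.

Covers the input-output curve (mean transcription rate vs repressor
concentration, pooled over nuclei near the repressor-domain centre), Hill
fits of that curve, the fraction of actively transcribing nuclei over
time, reactivation response times after optogenetic repressor export, the
memorylessness regression (response time vs prior silent duration, with an
F-test of the slope), exponential export/recovery kinetics fits, and
nucleus-level (cluster) bootstrap standard errors.

Frames within a nucleus are autocorrelated, so every bootstrap here
resamples nuclei, not frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
import statsmodels.api as sm

__all__ = [
    "InputOutputCurve",
    "HillFit",
    "EmptyWindowError",
    "compute_io_curve",
    "fit_hill",
    "fraction_active_timecourse",
    "extract_reactivation_times",
    "reactivation_cdf",
    "memorylessness_regression",
    "fit_exponential_kinetics",
    "bootstrap_se",
]


class EmptyWindowError(ValueError):
    """No nuclei (or no qualifying records) in the requested selection."""


@dataclass
class InputOutputCurve:
    """Binned mean transcription rate vs repressor concentration."""

    bin_centers: np.ndarray  # au
    mean_rate: np.ndarray    # au (MS2 proxy of the transcription rate)
    se: np.ndarray           # au, cluster-bootstrap standard error
    n_points: np.ndarray     # frames per bin
    bin_width: float = np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center_au": self.bin_centers,
                "mean_rate_au": self.mean_rate,
                "se_au": self.se,
                "n": self.n_points,
            }
        )


@dataclass
class HillFit:
    """Result of fitting ``amplitude * K_D**H / (c**H + K_D**H) + baseline``."""

    amplitude: float
    K_D: float
    H: float
    baseline: float
    se: dict = field(default_factory=dict)
    converged: bool = True
    message: str = ""

    def predict(self, c):
        c = np.asarray(c, dtype=float)
        num = self.K_D ** self.H
        return self.amplitude * num / (c ** self.H + num) + self.baseline


def _nucleus_ap(df: pd.DataFrame) -> pd.Series:
    return df.groupby("nucleus_id")["ap_offset_percent_EL"].first()


def compute_io_curve(
    traces: pd.DataFrame,
    ap_window: tuple[float, float] = (-2.0, 2.0),
    bin_width: float = 0.5,
    min_per_bin: int = 50,
    n_boot: int = 100,
    seed: int = 0,
) -> InputOutputCurve:
    """Pool (knirps, ms2) frames of nuclei inside the AP window and bin by
    repressor concentration; errors are nucleus-level bootstrap SEs.

    Bins with fewer than ``min_per_bin`` frames are suppressed.
    """
    ap = _nucleus_ap(traces)
    keep = ap.index[(ap >= ap_window[0]) & (ap <= ap_window[1])]
    if len(keep) == 0:
        raise EmptyWindowError("no nuclei inside the AP window")
    sub = traces[traces["nucleus_id"].isin(keep)]
    sub = sub.dropna(subset=["knirps_au", "ms2_au"])
    if len(sub) == 0:
        raise EmptyWindowError("no usable frames inside the AP window")
    c = sub["knirps_au"].to_numpy(float)
    y = sub["ms2_au"].to_numpy(float)
    lo = np.floor(c.min() / bin_width) * bin_width
    hi = np.ceil(c.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if edges.size < 2:
        edges = np.array([lo, lo + bin_width])
    idx = np.clip(np.digitize(c, edges) - 1, 0, edges.size - 2)
    n_bins = edges.size - 1

    nuc_codes, nuc_ids = pd.factorize(sub["nucleus_id"])
    n_nuc = len(nuc_ids)
    # per-nucleus per-bin sufficient statistics for the cluster bootstrap
    flat = nuc_codes * n_bins + idx
    sums = np.bincount(flat, weights=y, minlength=n_nuc * n_bins).reshape(
        n_nuc, n_bins
    )
    counts = np.bincount(flat, minlength=n_nuc * n_bins).reshape(n_nuc, n_bins)

    tot_counts = counts.sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = sums.sum(axis=0) / tot_counts
    se = np.full(n_bins, np.nan)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        reps = np.empty((n_boot, n_bins))
        for b in range(n_boot):
            mult = np.bincount(
                rng.integers(0, n_nuc, size=n_nuc), minlength=n_nuc
            ).astype(float)
            cs = mult @ counts
            with np.errstate(invalid="ignore"):
                reps[b] = (mult @ sums) / cs
        se = np.nanstd(reps, axis=0, ddof=1)
    ok = tot_counts >= min_per_bin
    centers = (edges[:-1] + edges[1:]) / 2
    return InputOutputCurve(
        bin_centers=centers[ok],
        mean_rate=means[ok],
        se=se[ok],
        n_points=tot_counts[ok],
        bin_width=bin_width,
    )


def fit_hill(
    curve: InputOutputCurve,
    fix_baseline: bool = True,
    n_starts: int = 8,
    seed: int = 0,
) -> HillFit:
    """Weighted least-squares Hill fit of the input-output curve.

    Weights are ``1/se**2`` where finite positive SEs are available,
    otherwise the fit is unweighted. Multi-start optimization over
    log-spaced midpoints; parameter SEs from the local curvature.
    """
    c = np.asarray(curve.bin_centers, dtype=float)
    y = np.asarray(curve.mean_rate, dtype=float)
    if c.size < 5:
        raise ValueError("need at least 5 informative bins spanning the transition")
    se = np.asarray(curve.se, dtype=float)
    use_w = np.all(np.isfinite(se)) and np.all(se > 0)
    w = 1.0 / se if use_w else np.ones_like(y)

    span = y.max() - y.min()
    if span <= 1e-9 * max(1.0, abs(y).max()):
        return HillFit(
            amplitude=0.0,
            K_D=np.nan,
            H=np.nan,
            baseline=float(y.mean()),
            converged=False,
            message="flat curve: K_D and H unidentifiable",
        )

    def residuals(theta):
        log_a, log_kd, log_h = theta[:3]
        baseline = 0.0 if fix_baseline else theta[3]
        a, h = np.exp(log_a), np.exp(log_h)
        # kd**h / (c**h + kd**h) as a logistic in log c (overflow-safe)
        z = np.full_like(c, -np.inf)
        np.log(c, out=z, where=c > 0)
        pred = a * expit(-h * (z - log_kd))
        return w * (pred + baseline - y)

    rng = np.random.default_rng(seed)
    c_pos = c[c > 0]
    kd_grid = np.exp(
        np.linspace(np.log(c_pos.min() + 1e-6), np.log(c_pos.max()), max(n_starts, 2))
    )
    best = None
    for i, kd0 in enumerate(kd_grid):
        h0 = float(rng.choice([1.0, 2.0, 4.0, 8.0]))
        theta0 = [np.log(max(span, 1e-6)), np.log(kd0), np.log(h0)]
        if not fix_baseline:
            theta0.append(y.min())
        try:
            res = optimize.least_squares(residuals, theta0, method="lm", max_nfev=2000)
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        return HillFit(
            amplitude=np.nan,
            K_D=np.nan,
            H=np.nan,
            baseline=np.nan,
            converged=False,
            message="no start converged",
        )
    log_a, log_kd, log_h = best.x[:3]
    baseline = 0.0 if fix_baseline else float(best.x[3])
    a, kd, h = np.exp([log_a, log_kd, log_h])

    # SEs from the Jacobian at the optimum (delta method for the log params)
    se_out = {}
    dof = max(c.size - best.x.size, 1)
    try:
        J = best.jac
        s2 = 2 * best.cost / dof
        cov = s2 * np.linalg.inv(J.T @ J)
        log_se = np.sqrt(np.clip(np.diag(cov), 0, None))
        se_out = {
            "amplitude": a * log_se[0],
            "K_D": kd * log_se[1],
            "H": h * log_se[2],
        }
        if not fix_baseline:
            se_out["baseline"] = float(log_se[3])
    except np.linalg.LinAlgError:
        pass
    return HillFit(
        amplitude=float(a),
        K_D=float(kd),
        H=float(h),
        baseline=baseline,
        se=se_out,
        converged=True,
    )


def fraction_active_timecourse(
    traces: pd.DataFrame,
    threshold: float,
    n_boot: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-frame fraction of nuclei with MS2 signal at or above threshold.

    Frames with no observed nuclei yield NaN. Returns columns
    ``t_sec, fraction_active, se, n``.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    sub = traces.dropna(subset=["ms2_au"]).copy()
    sub["active"] = (sub["ms2_au"] >= threshold).astype(float)
    times = np.sort(traces["t_sec"].unique())
    wide = sub.pivot_table(
        index="nucleus_id", columns="t_sec", values="active", sort=True
    ).reindex(columns=times)
    arr = wide.to_numpy(float)
    n = np.sum(np.isfinite(arr), axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        frac = np.nanmean(np.where(np.isfinite(arr), arr, np.nan), axis=0)
    frac = np.where(n > 0, frac, np.nan)
    se = np.full(times.size, np.nan)
    if n_boot > 0 and arr.shape[0] >= 2:
        rng = np.random.default_rng(seed)
        reps = np.empty((n_boot, times.size))
        n_nuc = arr.shape[0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for b in range(n_boot):
                pick = rng.integers(0, n_nuc, size=n_nuc)
                reps[b] = np.nanmean(arr[pick], axis=0)
        se = np.nanstd(reps, axis=0, ddof=1)
    return pd.DataFrame(
        {"t_sec": times, "fraction_active": frac, "se": se, "n": n}
    )


def extract_reactivation_times(
    traces: pd.DataFrame,
    threshold: float,
    min_silent: float = 2.0,
) -> pd.DataFrame:
    """Per-nucleus silent-duration / reactivation response-time records.

    Only nuclei continuously below ``threshold`` for at least ``min_silent``
    minutes immediately before the perturbation qualify (this excludes loci
    that were transiently OFF due to bursting). The response time is the
    interval from the perturbation to the first frame at or above
    threshold; nuclei that never reactivate within the movie are returned
    with ``censored = True``. ``silent_duration`` is the time since the
    last suprathreshold frame (or since the start of the movie).
    """
    records = []
    for nid, g in traces.groupby("nucleus_id"):
        tp = g["t_perturb_sec"].iloc[0]
        if not np.isfinite(tp):
            continue
        g = g.sort_values("t_sec")
        t = g["t_sec"].to_numpy(float)
        y = g["ms2_au"].to_numpy(float)
        pre = t < tp
        if not pre.any():
            continue
        active_pre = np.isfinite(y[pre]) & (y[pre] >= threshold)
        t_pre = t[pre]
        if active_pre.any():
            last_active = t_pre[active_pre][-1]
            silent_min = (tp - last_active) / 60.0
        else:
            silent_min = (tp - t_pre[0]) / 60.0
        if silent_min < min_silent:
            continue
        post = t >= tp
        active_post = np.isfinite(y[post]) & (y[post] >= threshold)
        if active_post.any():
            t_first = t[post][active_post][0]
            records.append(
                (nid, silent_min, (t_first - tp) / 60.0, False)
            )
        else:
            records.append((nid, silent_min, np.nan, True))
    if not records:
        raise EmptyWindowError("no nuclei qualify for reactivation analysis")
    return pd.DataFrame(
        records,
        columns=["nucleus_id", "silent_duration", "response_time", "censored"],
    )


def reactivation_cdf(
    records: pd.DataFrame, t_grid_min: Optional[np.ndarray] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Censoring-aware empirical CDF of reactivation response times.

    Censored records enter the denominator (so the CDF plateaus below 1
    when some loci never reactivate) but contribute no event times.
    """
    rt = records.loc[~records["censored"], "response_time"].to_numpy(float)
    n_total = len(records)
    if t_grid_min is None:
        t_grid_min = np.sort(rt)
    t_grid_min = np.asarray(t_grid_min, dtype=float)
    cdf = np.searchsorted(np.sort(rt), t_grid_min, side="right") / n_total
    return t_grid_min, cdf


def reactivation_summary(records: pd.DataFrame) -> dict:
    rt = records.loc[~records["censored"], "response_time"]
    return {
        "n_total": int(len(records)),
        "n_reactivated": int((~records["censored"]).sum()),
        "fraction_reactivated": float((~records["censored"]).mean()),
        "mean_response_min": float(rt.mean()),
        "median_response_min": float(rt.median()),
    }


def memorylessness_regression(
    records: pd.DataFrame,
    n_bins: int = 6,
    n_boot: int = 100,
    seed: int = 0,
) -> dict:
    """OLS of response time on prior silent duration, with an F-test of the
    slope model against an intercept-only model.

    Under memoryless reactivation the response time is independent of how
    long the locus was silent, so the slope is zero and the p-value is
    uniform. Returns slope, intercept, p-value and binned means with
    cluster-bootstrap SEs for plotting.
    """
    rec = records.loc[~records["censored"]]
    x = rec["silent_duration"].to_numpy(float)
    y = rec["response_time"].to_numpy(float)
    if x.size < 10:
        raise ValueError("need at least 10 uncensored records")
    if np.ptp(x) == 0:
        raise ValueError("all silent durations identical: slope undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    rng = np.random.default_rng(seed)
    bins = []
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            continue
        yb = y[sel]
        if n_boot > 0 and yb.size >= 2:
            reps = [
                rng.choice(yb, size=yb.size, replace=True).mean()
                for _ in range(n_boot)
            ]
            se_b = float(np.std(reps, ddof=1))
        else:
            se_b = np.nan
        bins.append(
            {
                "bin_center": float((edges[b] + edges[b + 1]) / 2),
                "mean_response": float(yb.mean()),
                "se": se_b,
                "n": int(yb.size),
            }
        )
    return {
        "slope": float(model.params[1]),
        "intercept": float(model.params[0]),
        "p_value": float(model.f_pvalue),
        "f_statistic": float(model.fvalue),
        "n": int(x.size),
        "binned": pd.DataFrame(bins),
    }


def fit_exponential_kinetics(
    t: np.ndarray,
    y: np.ndarray,
    direction: str,
) -> dict:
    """Fit ``a + b * 2**(-t / t_half)`` to an export or recovery segment.

    ``direction='export'`` expects a decreasing signal (b > 0),
    ``'recovery'`` an increasing one (b < 0). Returns the half-time in the
    units of ``t`` with its SE, the asymptote ``a``, and a ``flagged``
    field when the segment's trend contradicts the requested direction or
    the segment spans fewer than three fitted half-times.
    """
    if direction not in ("export", "recovery"):
        raise ValueError("direction must be 'export' or 'recovery'")
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    t0 = t - t[0]
    trend = y[-1] - y[0]
    flagged = False
    msgs = []
    if direction == "export" and trend > 0:
        flagged = True
        msgs.append("signal increases but direction is 'export'")
    if direction == "recovery" and trend < 0:
        flagged = True
        msgs.append("signal decreases but direction is 'recovery'")

    span = y.max() - y.min()
    b0 = span if direction == "export" else -span
    a0 = y[-1]
    th0 = max((t0[-1] - t0[0]) / 4, np.finfo(float).tiny)

    def model(tt, a, b, th):
        return a + b * np.exp2(-tt / th)

    try:
        popt, pcov = optimize.curve_fit(
            model,
            t0,
            y,
            p0=[a0, b0, th0],
            bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError:
        return {
            "half_time": np.nan,
            "asymptote": np.nan,
            "se": np.nan,
            "flagged": True,
            "message": "fit did not converge",
        }
    a, b, th = popt
    se = float(np.sqrt(max(pcov[2, 2], 0)))
    if t0[-1] < 3 * th:
        flagged = True
        msgs.append("segment spans fewer than 3 half-times")
    return {
        "half_time": float(th),
        "asymptote": float(a),
        "amplitude": float(b),
        "se": se,
        "flagged": flagged,
        "message": "; ".join(msgs),
    }


def bootstrap_se(
    statistic: Callable,
    data: Sequence,
    n_boot: int = 100,
    seed: int = 0,
    ci: float = 0.95,
) -> dict:
    """Nucleus-level (cluster) bootstrap SE of ``statistic(data)``.

    ``data`` is a sequence of per-nucleus units (scalars or arrays); the
    statistic is applied to each resampled sequence. Deterministic given
    ``seed``.
    """
    data = list(data)
    n = len(data)
    if n < 3:
        raise ValueError("need at least 3 nuclei to bootstrap")
    if n_boot < 100:
        warnings.warn("n_boot < 100: bootstrap SE may be unreliable", RuntimeWarning)
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.integers(0, n, size=n)
        reps[b] = statistic([data[i] for i in pick])
    alpha = (1 - ci) / 2
    return {
        "se": float(np.std(reps, ddof=1)),
        "interval": (
            float(np.quantile(reps, alpha)),
            float(np.quantile(reps, 1 - alpha)),
        ),
        "replicates": reps,
    }
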