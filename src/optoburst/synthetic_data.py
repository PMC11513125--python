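"""Synthetic paired repressor / MS2 trace generation.

Emulates the statistical structure of two-colour live-imaging data from the
early fly embryo: a sigmoidal rise of nuclear repressor (Knirps)
concentration over nuclear cycle 14, graded plateau reduction under
low/high blue-light illumination, fast optogenetic nuclear export
(half-time ~10 s) and slower recovery (~60 s), two-state bursty
transcription whose switching rates depend on the instantaneous repressor
concentration, and an MS2 fluorescence readout with a ``w``-step
elongation memory, measurement noise and a detection threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from ._kernels import telegraph_paths
from .responses import HillResponse, DurationResponse, kon_response, koff_response

__all__ = [
    "TimeGrid",
    "KnirpsScenario",
    "PromoterPath",
    "TraceSetConfig",
    "CONDITIONS",
    "default_scenarios",
    "deterministic_knirps",
    "gen_knirps_trajectory",
    "simulate_promoter_path",
    "ms2_fluorescence",
    "ramp_kernel",
    "gen_trace_set",
    "simulate_discrete_traces",
    "write_traces",
    "read_traces",
    "traces_to_arrays",
]

CONDITIONS = ("no_light", "low", "high", "export_step", "export_recovery")
_PERTURBED = ("export_step", "export_recovery")

#: default multiplicative plateau reduction per illumination condition
ILLUMINATION_SCALES = {"no_light": 1.0, "low": 0.6, "high": 0.3}


@dataclass(frozen=True)
class TimeGrid:
    """Uniform observation grid with elongation memory.

    ``w * dt`` is the elongation time: the number of sampling steps an RNAP
    molecule remains visible at the locus after initiation (140 s at the
    defaults of 7 steps x 20 s).
    """

    dt: float = 20.0       # sampling interval, seconds
    t_start: float = 0.0   # seconds relative to transcription onset in nc14
    t_end: float = 2100.0  # seconds
    w: int = 7             # elongation memory, integer steps

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.w < 1:
            raise ValueError("w must be >= 1")
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")

    @property
    def n_frames(self) -> int:
        return int(round((self.t_end - self.t_start) / self.dt))

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds (left edge of each sampling interval)."""
        return self.t_start + self.dt * np.arange(self.n_frames)

    @property
    def dt_min(self) -> float:
        return self.dt / 60.0

    @property
    def elongation_time(self) -> float:
        """Elongation time in seconds."""
        return self.w * self.dt


@dataclass(frozen=True)
class KnirpsScenario:
    """Parametrization of one nuclear-repressor concentration scenario.

    The unperturbed concentration follows a logistic rise
    ``scale * c_max / (1 + exp(-rise_sharpness * (t - t_half_rise)))`` with
    ``t`` in minutes. Illumination scales the plateau multiplicatively.
    Export decays exponentially toward ``c_residual`` with half-time
    ``t_half_export``; recovery relaxes back toward the unperturbed curve
    with half-time ``t_half_import``.
    """

    condition: str = "no_light"
    c_max: float = 8.0               # plateau concentration, au
    t_half_rise: float = 9.0         # time of half-maximal rise, minutes
    rise_sharpness: float = 1.0 / 3  # logistic steepness, per minute
    illumination_scale: float = 1.0  # plateau fraction in [0, 1]
    t_perturb: Optional[float] = None  # perturbation onset, minutes
    t_recover: Optional[float] = None  # light-off time, minutes (recovery)
    t_half_export: float = 10.0      # seconds
    t_half_import: float = 60.0      # seconds
    c_residual: float = 0.5          # post-export floor, au
    cell_to_cell_cv: float = 0.15    # CV of the per-nucleus plateau factor
    noise_sd: float = 0.3            # additive observation noise, au

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if not 0.0 <= self.illumination_scale <= 1.0:
            raise ValueError("illumination_scale must lie in [0, 1]")
        if not 0.0 <= self.c_residual <= self.c_max:
            raise ValueError("require 0 <= c_residual <= c_max")
        if self.t_half_export <= 0 or self.t_half_import <= 0:
            raise ValueError("half-times must be positive")


def default_scenarios(
    c_max: float = 8.0,
    t_perturb: float = 20.0,
    noise_sd: float = 0.3,
    cell_to_cell_cv: float = 0.15,
) -> dict[str, KnirpsScenario]:
    """The three illumination conditions plus the export-step experiment."""
    out = {}
    for cond in ("no_light", "low", "high"):
        out[cond] = KnirpsScenario(
            condition=cond,
            c_max=c_max,
            illumination_scale=ILLUMINATION_SCALES[cond],
            noise_sd=noise_sd,
            cell_to_cell_cv=cell_to_cell_cv,
        )
    out["export_step"] = KnirpsScenario(
        condition="export_step",
        c_max=c_max,
        t_perturb=t_perturb,
        noise_sd=noise_sd,
        cell_to_cell_cv=cell_to_cell_cv,
    )
    return out


@dataclass
class PromoterPath:
    """Binary promoter state path on a fine simulation grid."""

    states: np.ndarray  # int8, 0 = OFF, 1 = ON
    dt_fine: float      # seconds

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if not np.all((self.states == 0) | (self.states == 1)):
            raise ValueError("promoter states must be 0 or 1")
        if self.dt_fine <= 0:
            raise ValueError("dt_fine must be positive")


# ---------------------------------------------------------------------------
# repressor trajectories
# ---------------------------------------------------------------------------

def _unperturbed(scenario: KnirpsScenario, t_sec: np.ndarray) -> np.ndarray:
    t_min = t_sec / 60.0
    z = scenario.rise_sharpness * (t_min - scenario.t_half_rise)
    return scenario.illumination_scale * scenario.c_max / (1.0 + np.exp(-z))


def deterministic_knirps(scenario: KnirpsScenario, t_sec: np.ndarray) -> np.ndarray:
    """Noise-free population-level concentration curve at times ``t_sec``."""
    t_sec = np.asarray(t_sec, dtype=float)
    c = _unperturbed(scenario, t_sec)
    if scenario.condition not in _PERTURBED:
        return c
    if scenario.t_perturb is None:
        raise ValueError(f"{scenario.condition} requires t_perturb")
    tp_sec = scenario.t_perturb * 60.0
    c_at = float(_unperturbed(scenario, np.array([tp_sec]))[0])
    mask = t_sec >= tp_sec
    decay = scenario.c_residual + (c_at - scenario.c_residual) * np.exp2(
        -(t_sec - tp_sec) / scenario.t_half_export
    )
    c = np.where(mask, decay, c)
    if scenario.condition == "export_recovery":
        if scenario.t_recover is None:
            raise ValueError("export_recovery requires t_recover")
        tr_sec = scenario.t_recover * 60.0
        c_end = scenario.c_residual + (c_at - scenario.c_residual) * np.exp2(
            -(tr_sec - tp_sec) / scenario.t_half_export
        )
        base = _unperturbed(scenario, t_sec)
        rec = base - (base - c_end) * np.exp2(
            -(t_sec - tr_sec) / scenario.t_half_import
        )
        c = np.where(t_sec >= tr_sec, rec, c)
    return c


def gen_knirps_trajectory(
    scenario: KnirpsScenario,
    grid: TimeGrid,
    seed: int,
    return_clean: bool = False,
):
    """One nucleus's repressor concentration series on the observation grid.

    The per-nucleus plateau is scattered multiplicatively with
    ``cell_to_cell_cv``; observation noise is additive Gaussian truncated
    at zero. Deterministic given ``seed``.

    When ``return_clean`` is set, also returns the noise-free driving curve
    (including the per-nucleus plateau factor), which is the concentration
    the promoter actually responds to.
    """
    if scenario.condition in _PERTURBED:
        if scenario.t_perturb is None:
            raise ValueError(f"{scenario.condition} requires t_perturb")
        tp_sec = scenario.t_perturb * 60.0
        if not (grid.t_start <= tp_sec <= grid.t_end):
            raise ValueError("t_perturb outside the time grid")
    rng = np.random.default_rng(seed)
    factor = _plateau_factor(rng, scenario.cell_to_cell_cv)
    clean = factor * deterministic_knirps(scenario, grid.times)
    obs = clean + rng.normal(0.0, scenario.noise_sd, size=clean.shape)
    obs = np.clip(obs, 0.0, None)
    if return_clean:
        return obs, clean
    return obs


def _plateau_factor(rng: np.random.Generator, cv: float) -> float:
    if cv <= 0:
        return 1.0
    return float(max(rng.normal(1.0, cv), 0.2))


# ---------------------------------------------------------------------------
# promoter dynamics and MS2 readout
# ---------------------------------------------------------------------------

def upsample_step(series: np.ndarray, ratio: int) -> np.ndarray:
    """Step-hold upsampling of a frame-resolution series to the fine grid."""
    return np.repeat(np.asarray(series, dtype=float), ratio)


def simulate_promoter_path(
    kon_resp: HillResponse,
    koff_resp: DurationResponse,
    knirps: np.ndarray,
    r: float,
    dt_fine: float,
    seed: int,
    initial_state: Optional[int] = None,
) -> PromoterPath:
    """Simulate a time-inhomogeneous telegraph path driven by ``knirps``.

    ``knirps`` must be sampled on the fine grid (one value per ``dt_fine``
    step); rates are evaluated from the instantaneous concentration at the
    left edge of each step.
    """
    if dt_fine > 5.0:
        raise ValueError("dt_fine must be <= 5 s to resolve the fastest rates")
    knirps = np.asarray(knirps, dtype=float)
    kon = np.atleast_1d(kon_response(knirps, kon_resp))
    koff = np.atleast_1d(koff_response(knirps, koff_resp))
    dt_fine_min = dt_fine / 60.0
    max_rate = max(kon.max(), koff.max())
    if max_rate * dt_fine_min > 0.5:
        warnings.warn(
            "dt_fine * max(rate) > 0.5: Bernoulli discretization error may "
            "be appreciable",
            RuntimeWarning,
        )
    rng = np.random.default_rng(seed)
    if initial_state is None:
        p_on = kon[0] / (kon[0] + koff[0])
        s0 = np.array([rng.random() < p_on], dtype=np.int8)
    else:
        s0 = np.array([initial_state], dtype=np.int8)
    u = rng.random((1, knirps.size))
    states = telegraph_paths(
        kon[None, :], koff[None, :], dt_fine_min, u, s0
    )[0]
    return PromoterPath(states=states, dt_fine=dt_fine)


def ramp_kernel(w: int) -> np.ndarray:
    """Linear ramp over the first ceil(w/2) steps, mimicking progressive
    stem-loop synthesis; remaining steps at full weight."""
    n_ramp = int(np.ceil(w / 2))
    k = np.ones(w)
    # kernel index is the lag: recently initiated RNAPs (small lag) have
    # synthesised fewer stem-loops and contribute less signal
    k[:n_ramp] = np.linspace(1.0 / n_ramp, 1.0, n_ramp)
    return k


def _frame_occupancy(path: PromoterPath, grid: TimeGrid) -> np.ndarray:
    ratio = int(round(grid.dt / path.dt_fine))
    if abs(ratio * path.dt_fine - grid.dt) > 1e-9:
        raise ValueError("dt_fine must divide the frame interval")
    n = path.states.size // ratio
    if n * ratio != path.states.size:
        raise ValueError("path length is not a whole number of frames")
    return path.states[: n * ratio].reshape(n, ratio).mean(axis=1)


def ms2_fluorescence(
    path: PromoterPath,
    r: float,
    grid: TimeGrid,
    kernel: Optional[np.ndarray] = None,
) -> np.ndarray:
    """MS2 fluorescence from a promoter path.

    ``F(t) = r * dt * sum_i kappa_i * s(t - i dt)`` where ``s`` is the
    frame-averaged promoter occupancy and the kernel has length ``w``
    (uniform by default). Loci are dark before the movie starts, so the
    signal builds up over the first ``w`` frames.
    """
    if kernel is None:
        kernel = np.ones(grid.w)
    kernel = np.asarray(kernel, dtype=float)
    if kernel.size != grid.w:
        raise ValueError(f"kernel length {kernel.size} != w = {grid.w}")
    if np.any(kernel < 0) or np.any(kernel > 1):
        raise ValueError("kernel weights must lie in [0, 1]")
    occ = _frame_occupancy(path, grid) if path.dt_fine != grid.dt else (
        path.states.astype(float)
    )
    return r * grid.dt_min * np.convolve(occ, kernel)[: occ.size]


def fluorescence_from_occupancy(
    occ: np.ndarray, r: float, grid: TimeGrid, kernel: Optional[np.ndarray] = None
) -> np.ndarray:
    """Vectorised MS2 signal from frame occupancies, shape (n, T)."""
    if kernel is None:
        kernel = np.ones(grid.w)
    kernel = np.asarray(kernel, dtype=float)
    occ = np.asarray(occ, dtype=float)
    T = occ.shape[-1]
    padded = np.concatenate(
        [np.zeros(occ.shape[:-1] + (grid.w - 1,)), occ], axis=-1
    )
    windows = np.lib.stride_tricks.sliding_window_view(padded, grid.w, axis=-1)
    # window is ordered oldest..newest; kernel index i is the lag
    return r * grid.dt_min * windows @ kernel[::-1]


# ---------------------------------------------------------------------------
# trace-set generation
# ---------------------------------------------------------------------------

@dataclass
class TraceSetConfig:
    """Study conditions for a full synthetic trace set."""

    grid: TimeGrid = field(default_factory=TimeGrid)
    kon: HillResponse = field(
        default_factory=lambda: HillResponse(kon0=2.8, K_D=3.7, H=6.1)
    )
    koff: DurationResponse = field(
        default_factory=lambda: DurationResponse(
            koff_base=2.0, koff_floor=1.54, K_D_off=3.7, H_off=6.1
        )
    )
    r: float = 2.0                     # initiation rate while ON, au/min
    scenarios: dict[str, KnirpsScenario] = field(default_factory=default_scenarios)
    n_embryos: int = 4
    ap_window: tuple[float, float] = (-2.0, 2.0)  # % embryo length
    ms2_noise_sd: float = 0.3          # au
    detection_threshold: Optional[float] = None   # au; default 2 * ms2_noise_sd
    dt_fine: float = 2.0               # seconds

    def __post_init__(self) -> None:
        if self.detection_threshold is None:
            self.detection_threshold = 2.0 * self.ms2_noise_sd


def gen_trace_set(
    config: TraceSetConfig, n_nuclei: int, seed: int
) -> tuple[pd.DataFrame, dict]:
    """Generate ``n_nuclei`` traces per scenario plus a ground-truth ledger.

    Returns a tidy DataFrame (one row per nucleus per frame) and a ledger
    dict holding the generating parameters, per-nucleus plateau factors and
    true frame-resolution promoter occupancies. Per-nucleus random streams
    are derived from the master seed by counter, so any subset is
    reproducible.
    """
    if n_nuclei < 1:
        raise ValueError("n_nuclei must be >= 1")
    grid = config.grid
    t = grid.times
    ratio = int(round(grid.dt / config.dt_fine))
    frames = grid.n_frames
    rows = []
    truth_nuclei = {}
    true_paths = {}
    for ci, (cond, scenario) in enumerate(sorted(config.scenarios.items())):
        if scenario.condition in _PERTURBED and scenario.t_perturb is None:
            raise ValueError(f"scenario {cond} requires t_perturb")
        for j in range(n_nuclei):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(ci, j))
            )
            nucleus_id = f"{cond}_{j:04d}"
            embryo_id = f"{cond}_e{j % config.n_embryos}"
            ap = float(rng.uniform(*config.ap_window))
            factor = _plateau_factor(rng, scenario.cell_to_cell_cv)
            clean = factor * deterministic_knirps(scenario, t)
            knirps_obs = np.clip(
                clean + rng.normal(0.0, scenario.noise_sd, size=frames), 0.0, None
            )
            fine = upsample_step(clean, ratio)
            kon = np.atleast_1d(kon_response(fine, config.kon))
            koff = np.atleast_1d(koff_response(fine, config.koff))
            p_on0 = kon[0] / (kon[0] + koff[0])
            s0 = np.array([rng.random() < p_on0], dtype=np.int8)
            u = rng.random((1, fine.size))
            states = telegraph_paths(
                kon[None, :], koff[None, :], config.dt_fine / 60.0, u, s0
            )
            occ = states[0].reshape(frames, ratio).mean(axis=1)
            signal = fluorescence_from_occupancy(occ, config.r, grid)
            ms2 = np.clip(
                signal + rng.normal(0.0, config.ms2_noise_sd, size=frames),
                0.0,
                None,
            )
            tp_sec = (
                scenario.t_perturb * 60.0
                if scenario.t_perturb is not None
                else np.nan
            )
            rows.append(
                pd.DataFrame(
                    {
                        "nucleus_id": nucleus_id,
                        "embryo_id": embryo_id,
                        "condition": cond,
                        "ap_offset_percent_EL": ap,
                        "t_sec": t,
                        "knirps_au": knirps_obs,
                        "ms2_au": ms2,
                        "t_perturb_sec": tp_sec,
                    }
                )
            )
            truth_nuclei[nucleus_id] = {
                "plateau_factor": factor,
                "ap_offset_percent_EL": ap,
            }
            true_paths[nucleus_id] = occ
    df = pd.concat(rows, ignore_index=True)
    ledger = {
        "seed": seed,
        "params": {
            "kon": asdict(config.kon),
            "koff": asdict(config.koff),
            "r_au_per_min": config.r,
            "ms2_noise_sd_au": config.ms2_noise_sd,
            "detection_threshold_au": config.detection_threshold,
            "grid": asdict(grid),
            "dt_fine_sec": config.dt_fine,
            "scenarios": {k: asdict(v) for k, v in config.scenarios.items()},
        },
        "nuclei": truth_nuclei,
        "paths": true_paths,
    }
    return df, ledger


def simulate_discrete_traces(
    k_on: float,
    k_off: float,
    r: float,
    sigma: float,
    n_traces: int,
    n_frames: int,
    grid: TimeGrid,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Constant-rate traces at frame resolution (the compound-HMM generative
    process): a discrete two-state chain at the sampling interval, started
    from its stationary distribution with ``w - 1`` burn-in frames of
    history, and Gaussian emission noise.

    Returns ``(ms2, states)`` with shapes ``(n_traces, n_frames)``.
    """
    rng = np.random.default_rng(seed)
    T = n_frames + grid.w - 1
    kon = np.full((n_traces, T), float(k_on))
    koff = np.full((n_traces, T), float(k_off))
    p_on = k_on / (k_on + k_off)
    s0 = (rng.random(n_traces) < p_on).astype(np.int8)
    u = rng.random((n_traces, T))
    states = telegraph_paths(kon, koff, grid.dt_min, u, s0)
    kernel = np.ones(grid.w)
    counts = np.lib.stride_tricks.sliding_window_view(
        states.astype(float), grid.w, axis=1
    ) @ kernel
    signal = r * grid.dt_min * counts
    ms2 = signal + rng.normal(0.0, sigma, size=signal.shape)
    return ms2, states[:, grid.w - 1 :]


# ---------------------------------------------------------------------------
# trace file I/O
# ---------------------------------------------------------------------------

TRACE_COLUMNS = [
    "nucleus_id",
    "embryo_id",
    "condition",
    "ap_offset_percent_EL",
    "t_sec",
    "knirps_au",
    "ms2_au",
    "t_perturb_sec",
]


def write_traces(df: pd.DataFrame, path) -> None:
    """Write a trace table as delimited text (missing ms2 -> empty field)."""
    df.to_csv(path, index=False, columns=TRACE_COLUMNS, float_format="%.6g")


def read_traces(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace file missing columns: {sorted(missing)}")
    return df


def traces_to_arrays(df: pd.DataFrame, value: str = "ms2_au"):
    """Pivot a tidy trace table to (nucleus_ids, times, values[n, T])."""
    wide = df.pivot_table(
        index="nucleus_id", columns="t_sec", values=value, sort=True
    )
    return list(wide.index), wide.columns.to_numpy(float), wide.to_numpy(float)
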