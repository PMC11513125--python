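import numpy as np
import pandas as pd
import pytest
from scipy import stats

from optoburst import (
    DurationResponse,
    HillResponse,
    KnirpsScenario,
    PromoterPath,
    TimeGrid,
    TraceSetConfig,
    gen_knirps_trajectory,
    gen_trace_set,
    ms2_fluorescence,
    simulate_promoter_path,
)
from optoburst.synthetic_data import (
    CONDITIONS,
    default_scenarios,
    deterministic_knirps,
    fluorescence_from_occupancy,
    ramp_kernel,
    read_traces,
    simulate_discrete_traces,
    write_traces,
)
from optoburst.trace_analysis import fit_exponential_kinetics


class TestTimeGrid:
    def test_defaults(self, grid):
        assert grid.elongation_time == pytest.approx(140.0)
        assert grid.n_frames == 105
        assert grid.times[0] == 0.0
        assert np.allclose(np.diff(grid.times), 20.0)

    def test_invalid(self):
        with pytest.raises(ValueError):
            TimeGrid(dt=0)
        with pytest.raises(ValueError):
            TimeGrid(w=0)
        with pytest.raises(ValueError):
            TimeGrid(t_start=100.0, t_end=50.0)


class TestKnirpsTrajectories:
    def test_asymptote_equals_plateau(self, grid):
        sc = KnirpsScenario(condition="no_light", c_max=8.0, noise_sd=0.0,
                            cell_to_cell_cv=0.0)
        c = deterministic_knirps(sc, np.array([1e6]))
        assert c[0] == pytest.approx(8.0, abs=1e-6)

    def test_illumination_scales_plateau(self):
        t = np.array([1e6])
        for scale in (1.0, 0.6, 0.3):
            sc = KnirpsScenario(condition="no_light", c_max=8.0,
                                illumination_scale=scale)
            assert deterministic_knirps(sc, t)[0] == pytest.approx(8.0 * scale,
                                                                   abs=1e-6)

    def test_export_one_half_time(self):
        sc = KnirpsScenario(condition="export_step", c_max=8.0, t_perturb=20.0,
                            c_residual=0.0, t_half_export=10.0)
        tp = 20.0 * 60.0
        c_at, c_half = deterministic_knirps(sc, np.array([tp, tp + 10.0]))
        assert c_half == pytest.approx(c_at / 2.0, rel=1e-9)

    def test_export_decays_to_residual(self):
        sc = KnirpsScenario(condition="export_step", c_max=8.0, t_perturb=20.0,
                            c_residual=0.5)
        c = deterministic_knirps(sc, np.array([20.0 * 60 + 600.0]))
        assert c[0] == pytest.approx(0.5, abs=1e-6)

    def test_export_recovery_roundtrip_half_times(self):
        # noise-free export + recovery segments, refit with the kinetics
        # fitter, should return the generating half-times (10 s, 60 s)
        sc = KnirpsScenario(condition="export_recovery", c_max=8.0,
                            t_perturb=20.0, t_recover=24.0,
                            t_half_export=10.0, t_half_import=60.0,
                            noise_sd=0.0, cell_to_cell_cv=0.0)
        t = np.arange(0.0, 2100.0, 1.0)
        c = deterministic_knirps(sc, t)
        exp_seg = (t >= 20 * 60) & (t < 24 * 60)
        rec_seg = t >= 24 * 60
        fit_e = fit_exponential_kinetics(t[exp_seg], c[exp_seg], "export")
        fit_r = fit_exponential_kinetics(t[rec_seg], c[rec_seg], "recovery")
        assert fit_e["half_time"] == pytest.approx(10.0, rel=0.02)
        assert fit_r["half_time"] == pytest.approx(60.0, rel=0.05)

    def test_trajectory_deterministic_given_seed(self, grid):
        sc = default_scenarios()["no_light"]
        a = gen_knirps_trajectory(sc, grid, seed=5)
        b = gen_knirps_trajectory(sc, grid, seed=5)
        assert np.array_equal(a, b)
        c = gen_knirps_trajectory(sc, grid, seed=6)
        assert not np.array_equal(a, c)

    def test_trajectory_nonnegative(self, grid):
        sc = KnirpsScenario(condition="no_light", noise_sd=2.0)
        c = gen_knirps_trajectory(sc, grid, seed=1)
        assert np.all(c >= 0)

    def test_perturbation_outside_grid_rejected(self, grid):
        sc = KnirpsScenario(condition="export_step", t_perturb=100.0)
        with pytest.raises(ValueError):
            gen_knirps_trajectory(sc, grid, seed=0)

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            KnirpsScenario(condition="bogus")


class TestPromoterSimulation:
    def test_stationary_on_fraction(self, rng):
        # constant rates k_on = k_off = 2/min -> ON fraction 1/2
        kon = HillResponse(kon0=2.0, K_D=1.0, H=1.0)
        koff = DurationResponse(koff_base=2.0, koff_floor=2.0, K_D_off=1.0,
                                H_off=1.0)
        n_paths, t_total_min, dt_fine = 200, 30.0, 2.0
        frac = []
        for i in range(n_paths):
            knirps = np.zeros(int(t_total_min * 60 / dt_fine))
            path = simulate_promoter_path(kon, koff, knirps, r=1.0,
                                          dt_fine=dt_fine, seed=1000 + i)
            frac.append(path.states.mean())
        # effective sample size ~ total time / correlation time (0.25 min)
        n_eff = n_paths * t_total_min / 0.25
        se = np.sqrt(0.25 / n_eff)
        assert abs(np.mean(frac) - 0.5) < 3 * se

    def test_off_dwells_exponential(self):
        # OFF dwell times are geometric with p = 1 - exp(-k dt); with
        # uniform jitter inside the step they match the exponential with
        # mean 1/k_on to O((k dt)^2). KS test at alpha = 0.01.
        k_on, k_off, dt_fine = 2.0, 2.0, 2.0
        kon = HillResponse(kon0=k_on, K_D=1.0, H=1.0)
        koff = DurationResponse(koff_base=k_off, koff_floor=k_off, K_D_off=1.0,
                                H_off=1.0)
        dwells = []
        i = 0
        while len(dwells) < 5000:
            knirps = np.zeros(30000)
            path = simulate_promoter_path(kon, koff, knirps, r=1.0,
                                          dt_fine=dt_fine, seed=7000 + i)
            s = path.states
            edges = np.flatnonzero(np.diff(s) != 0) + 1
            bounds = np.concatenate([[0], edges, [s.size]])
            for a, b in zip(bounds[:-1], bounds[1:]):
                if s[a] == 0 and a != 0 and b != s.size:
                    dwells.append(b - a)
            i += 1
        rng = np.random.default_rng(0)
        steps = np.asarray(dwells[:5000], dtype=float)
        t_min = (steps - rng.random(steps.size)) * dt_fine / 60.0
        res = stats.kstest(t_min, "expon", args=(0, 1.0 / k_on))
        assert res.pvalue > 0.01

    def test_absorbing_when_kon_zero(self):
        kon = HillResponse(kon0=2.8, K_D=0.01, H=8.0)  # k_on ~ 0 at c = 10
        koff = DurationResponse(koff_base=2.0, koff_floor=2.0, K_D_off=1.0,
                                H_off=1.0)
        knirps = np.full(2000, 10.0)
        path = simulate_promoter_path(kon, koff, knirps, r=1.0, dt_fine=2.0,
                                      seed=3, initial_state=0)
        assert path.states.sum() == 0

    def test_dt_fine_too_coarse_rejected(self):
        kon = HillResponse(kon0=1.0, K_D=1.0, H=1.0)
        koff = DurationResponse(koff_base=1.0, koff_floor=1.0, K_D_off=1.0,
                                H_off=1.0)
        with pytest.raises(ValueError):
            simulate_promoter_path(kon, koff, np.zeros(10), r=1.0,
                                   dt_fine=10.0, seed=0)

    def test_fast_rate_warns(self):
        kon = HillResponse(kon0=20.0, K_D=1.0, H=1.0)
        koff = DurationResponse(koff_base=20.0, koff_floor=20.0, K_D_off=1.0,
                                H_off=1.0)
        with pytest.warns(RuntimeWarning, match="discretization"):
            simulate_promoter_path(kon, koff, np.zeros(100), r=1.0,
                                   dt_fine=2.0, seed=0)

    def test_dt_halving_invariant(self, grid):
        # halving dt_fine changes the mean simulated fluorescence by < 1%
        kon = HillResponse(kon0=2.8, K_D=3.7, H=6.1)
        koff = DurationResponse(koff_base=2.0, koff_floor=1.54, K_D_off=3.7,
                                H_off=6.1)
        means = {}
        for dt_fine in (2.0, 1.0):
            ratio = int(grid.dt / dt_fine)
            tot = 0.0
            for i in range(400):
                knirps = np.full(grid.n_frames * ratio, 2.0)
                path = simulate_promoter_path(kon, koff, knirps, r=2.0,
                                              dt_fine=dt_fine, seed=50_000 + i)
                tot += ms2_fluorescence(path, 2.0, grid).mean()
            means[dt_fine] = tot / 400
        assert abs(means[2.0] - means[1.0]) / means[1.0] < 0.01


class TestMs2Fluorescence:
    def test_plateau_closed_form(self, grid):
        path = PromoterPath(states=np.ones(grid.n_frames, dtype=np.int8),
                            dt_fine=grid.dt)
        f = ms2_fluorescence(path, r=2.0, grid=grid)
        # r * dt * w = 2 * (1/3) * 7 = 4.667 au once the buffer is full
        assert f[-1] == pytest.approx(2.0 * grid.dt_min * grid.w)
        assert f[-1] == pytest.approx(4.667, abs=1e-3)

    def test_always_off_is_zero(self, grid):
        path = PromoterPath(states=np.zeros(grid.n_frames, dtype=np.int8),
                            dt_fine=grid.dt)
        assert np.all(ms2_fluorescence(path, r=2.0, grid=grid) == 0)

    def test_impulse_response_boxcar(self, grid):
        s = np.zeros(grid.n_frames, dtype=np.int8)
        s[30] = 1
        path = PromoterPath(states=s, dt_fine=grid.dt)
        f = ms2_fluorescence(path, r=2.0, grid=grid)
        expected = np.zeros(grid.n_frames)
        expected[30:30 + grid.w] = 2.0 * grid.dt_min
        assert np.allclose(f, expected)

    def test_linear_in_r_and_additive(self, grid):
        rng = np.random.default_rng(4)
        s1 = (rng.random(grid.n_frames) < 0.3).astype(np.int8)
        s2 = ((rng.random(grid.n_frames) < 0.3) & (s1 == 0)).astype(np.int8)
        f = lambda s, r: ms2_fluorescence(
            PromoterPath(states=s, dt_fine=grid.dt), r, grid
        )
        assert np.allclose(f(s1, 4.0), 2.0 * f(s1, 2.0))
        assert np.allclose(f(s1, 2.0) + f(s2, 2.0), f(s1 + s2, 2.0))

    def test_kernel_length_mismatch_rejected(self, grid):
        path = PromoterPath(states=np.ones(grid.n_frames, dtype=np.int8),
                            dt_fine=grid.dt)
        with pytest.raises(ValueError):
            ms2_fluorescence(path, 2.0, grid, kernel=np.ones(3))

    def test_ramp_kernel_shape(self):
        k = ramp_kernel(7)
        assert k.size == 7
        assert k[0] < k[3] == 1.0
        assert np.all((k >= 0) & (k <= 1))

    def test_vectorized_matches_single(self, grid):
        rng = np.random.default_rng(9)
        occ = rng.random((5, grid.n_frames))
        vec = fluorescence_from_occupancy(occ, 2.0, grid)
        for i in range(5):
            # occupancy path at frame resolution, same convolution
            single = 2.0 * grid.dt_min * np.convolve(
                occ[i], np.ones(grid.w)
            )[: grid.n_frames]
            assert np.allclose(vec[i], single)


class TestTraceSet:
    def test_rejects_no_nuclei(self):
        with pytest.raises(ValueError):
            gen_trace_set(TraceSetConfig(), n_nuclei=0, seed=1)

    def test_schema_and_conditions(self, small_trace_set, grid):
        df, ledger = small_trace_set
        assert set(df["condition"].unique()) == {"no_light", "low", "high",
                                                 "export_step"}
        n_conditions = df["condition"].nunique()
        assert len(df) == n_conditions * 20 * grid.n_frames
        for cond in CONDITIONS[:3]:
            sub = df[df["condition"] == cond]
            assert sub["t_perturb_sec"].isna().all()
        exp = df[df["condition"] == "export_step"]
        assert np.all(exp["t_perturb_sec"] == 20.0 * 60)

    def test_reproducible_and_subset_stable(self):
        cfg = TraceSetConfig()
        df1, _ = gen_trace_set(cfg, n_nuclei=4, seed=77)
        df2, _ = gen_trace_set(cfg, n_nuclei=4, seed=77)
        pd.testing.assert_frame_equal(df1, df2)
        # per-nucleus substreams: the first nuclei of a larger set match
        df3, _ = gen_trace_set(cfg, n_nuclei=6, seed=77)
        ids = df1["nucleus_id"].unique()
        pd.testing.assert_frame_equal(
            df1.reset_index(drop=True),
            df3[df3["nucleus_id"].isin(ids)].reset_index(drop=True),
        )

    def test_constitutive_limit_plateaus(self, grid):
        # k_on huge, k_off ~ 0, no noise -> all traces plateau at r*dt*w
        cfg = TraceSetConfig(
            kon=HillResponse(kon0=500.0, K_D=1e6, H=1.0),
            koff=DurationResponse(koff_base=1e-9, koff_floor=1e-9,
                                  K_D_off=1.0, H_off=1.0),
            ms2_noise_sd=1e-12,
            scenarios={"no_light": KnirpsScenario(noise_sd=0.0)},
            dt_fine=0.5,
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            df, _ = gen_trace_set(cfg, n_nuclei=3, seed=5)
        tail = df[df["t_sec"] > grid.elongation_time]["ms2_au"]
        assert np.allclose(tail, 2.0 * grid.dt_min * grid.w, rtol=1e-6)

    def test_ledger_contents(self, small_trace_set, grid):
        df, ledger = small_trace_set
        assert ledger["params"]["kon"]["kon0"] == 2.8
        assert ledger["params"]["koff"]["koff_floor"] == 1.54
        some_id = df["nucleus_id"].iloc[0]
        assert some_id in ledger["paths"]
        assert ledger["paths"][some_id].shape == (grid.n_frames,)
        assert some_id in ledger["nuclei"]

    def test_roundtrip_io(self, tmp_path, small_trace_set):
        df, _ = small_trace_set
        p = tmp_path / "traces.csv"
        write_traces(df, p)
        back = read_traces(p)
        assert list(back.columns) == list(df.columns)
        assert len(back) == len(df)
        assert np.allclose(back["ms2_au"], df["ms2_au"], rtol=1e-4, atol=1e-5)

    def test_read_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({"a": [1]}).to_csv(p, index=False)
        with pytest.raises(ValueError, match="missing columns"):
            read_traces(p)


class TestDiscreteTraces:
    def test_shapes_and_determinism(self, grid):
        ms2, states = simulate_discrete_traces(2.3, 2.0, 2.0, 0.3, 10, 45,
                                               grid, seed=2)
        assert ms2.shape == (10, 45)
        assert states.shape == (10, 45)
        ms2b, _ = simulate_discrete_traces(2.3, 2.0, 2.0, 0.3, 10, 45, grid,
                                           seed=2)
        assert np.array_equal(ms2, ms2b)

    def test_mean_signal_matches_stationary_occupancy(self, grid):
        k_on, k_off, r = 2.3, 2.0, 2.0
        ms2, states = simulate_discrete_traces(k_on, k_off, r, 1e-9, 400, 200,
                                               grid, seed=8)
        p = k_on / (k_on + k_off)
        expected = r * grid.dt_min * grid.w * p
        assert ms2.mean() == pytest.approx(expected, rel=0.02)
        assert states.mean() == pytest.approx(p, rel=0.02)
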