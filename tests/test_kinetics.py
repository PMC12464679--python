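"""Kinetics: ODE solutions vs matrix-exponential oracles, populations, RMSE."""

import numpy as np
import pytest
from scipy.linalg import expm

from tocky.kinetics import (KineticParams, TransientParams, rmse,
                            population_to_angles, simulate_constant,
                            simulate_transient, synthesize_population,
                            transient_input)

P = KineticParams()


def chain_matrix(p: KineticParams) -> np.ndarray:
    """System matrix of the (C, B, M, R) chain, X as an appended constant."""
    return np.array(
        [
            [-p.kb, 0.0, 0.0, 0.0, p.d],
            [p.kb, -p.ki, 0.0, 0.0, 0.0],
            [0.0, p.ki, -p.kr, 0.0, 0.0],
            [0.0, 0.0, p.kr, -p.s, 0.0],
            [0.0, 0.0, 0.0, 0.0, 0.0],
        ]
    )


def constant_model_oracle(X0, times, p=P):
    """Matrix-exponential solution of the constant-transcription chain."""
    A = chain_matrix(p)
    y0 = np.array([0.0, 0.0, 0.0, 0.0, X0])
    return np.array([expm(A * t) @ y0 for t in times])[:, :4]


def transient_direct_oracle(times, p=P, tp=TransientParams(), step=0.0005):
    """Piecewise matrix-exponential oracle for the forced (direct) mode.

    During the spike window the forcing is held at its midpoint over tiny
    substeps (zero-order hold, O(step^2) accurate); after the window closes
    the homogeneous system is propagated exactly with expm.  Independent of
    the package's solve_ivp path.
    """
    A = chain_matrix(p)[:4, :4]
    eAs = expm(A * step)
    Ainv_term = np.linalg.solve(A, eAs - np.eye(4))
    times = np.asarray(times, float)
    # forced phase: integrate from 0 to toff with midpoint zero-order hold
    y = np.zeros(4)
    t = 0.0
    forced: list[tuple[float, np.ndarray]] = [(0.0, y.copy())]
    while t < tp.toff - 1e-12:
        g = np.array([p.d * transient_input(t + step / 2, tp), 0.0, 0.0, 0.0])
        y = eAs @ y + Ainv_term @ g
        t += step
        forced.append((t, y.copy()))
    forced_t = np.array([ft for ft, _ in forced])
    forced_y = np.array([fy for _, fy in forced])
    out = []
    for tt in times:
        if tt <= tp.toff:
            out.append(forced_y[np.argmin(np.abs(forced_t - tt))])
        else:
            out.append(expm(A * (tt - t)) @ y)
    return np.array(out)


class TestConstantModel:
    def test_zero_transcription_stays_zero(self):
        traj = simulate_constant(0.0, t_end=24.0, dt=1.0)
        assert np.all(traj.to_frame()[["C", "B", "M", "R"]].to_numpy() == 0.0)

    def test_steady_states_match_closed_form(self):
        # slowest rate is s = 0.048/h; by 400 h transients have decayed
        traj = simulate_constant(100.0, t_end=400.0, dt=2.0)
        assert traj.C[-1] == pytest.approx(0.3 * 100 / 8.7, rel=1e-4)
        assert traj.B[-1] == pytest.approx(0.3 * 100 / 0.78, rel=1e-4)
        assert traj.M[-1] == pytest.approx(0.3 * 100 / 0.14, rel=1e-4)
        assert traj.R[-1] == pytest.approx(625.0, rel=1e-4)

    def test_matches_matrix_exponential_oracle(self):
        times = np.arange(0.0, 168.0 + 0.5, 4.0)
        traj = simulate_constant(250.0, t_end=168.0, dt=4.0)
        oracle = constant_model_oracle(250.0, times)
        sim = np.column_stack([traj.C, traj.B, traj.M, traj.R])
        np.testing.assert_allclose(sim, oracle, rtol=1e-6, atol=1e-8)

    def test_states_nonnegative(self):
        traj = simulate_constant(500.0, t_end=168.0, dt=0.5)
        assert traj.to_frame()[["C", "B", "M", "R"]].min().min() >= 0.0

    def test_blue_red_ratio_converges_to_s_over_ki(self):
        traj = simulate_constant(100.0, t_end=600.0, dt=5.0)
        assert traj.B[-1] / traj.R[-1] == pytest.approx(P.s / P.ki, rel=1e-3)

    def test_negative_x0_rejected(self):
        with pytest.raises(ValueError):
            simulate_constant(-1.0)


class TestTransientInput:
    def test_peak_value(self):
        assert transient_input(2.5) == 10.0

    def test_zero_outside_window(self):
        assert transient_input(0.4) == 0.0
        assert transient_input(6.01) == 0.0
        assert transient_input(0.5) > 0.0

    def test_gaussian_decay_value(self):
        assert transient_input(4.0) == pytest.approx(10 * np.exp(-1.8 * 2.25), rel=1e-12)

    def test_window_ordering_validated(self):
        with pytest.raises(ValueError):
            TransientParams(ton=3.0, tpeak=2.5)


class TestTransientModel:
    def test_default_grid_has_481_points(self):
        traj = simulate_transient()
        assert len(traj.time) == 481
        assert traj.time[0] == 0.0 and traj.time[-1] == pytest.approx(48.0)

    def test_zero_spike_all_zero(self):
        tp = TransientParams(cspike=0.0)
        traj = simulate_transient(tp=tp)
        assert np.all(traj.to_frame()[["C", "B", "M", "R"]].to_numpy() == 0.0)

    def test_direct_mode_matches_forced_oracle(self):
        times = np.arange(0.0, 48.0 + 0.05, 2.0)
        traj = simulate_transient(t_end=48.0, dt=2.0, x_mode="direct")
        oracle = transient_direct_oracle(times)
        sim = np.column_stack([traj.C, traj.B, traj.M, traj.R])
        scale = np.abs(oracle).max()
        np.testing.assert_allclose(sim, oracle, rtol=1e-5, atol=1e-5 * scale)

    def test_ode_mode_honours_kdeg(self):
        direct = simulate_transient(x_mode="direct")
        ode = simulate_transient(x_mode="ode")
        assert ode.meta["x_mode"] == "ode"
        # in ode mode X persists after the window closes (first-order decay)
        after = ode.time > 10.0
        assert np.all(ode.X[after] > 0)
        assert np.all(direct.X[direct.time > 6.0] == 0.0)

    def test_blue_red_ratio_decreasing_after_spike(self):
        traj = simulate_transient()
        # B decays at ~ki; restrict to where it is still numerically resolved
        late = (traj.time > TransientParams().toff + 1.0) & (traj.B > 1e-9)
        ratio = traj.B[late] / traj.R[late]
        assert np.all(np.diff(ratio) < 0)

    def test_grid_refinement_convergence(self):
        coarse = simulate_transient(dt=0.2)
        fine = simulate_transient(dt=0.1)
        common = np.isin(np.round(fine.time, 9), np.round(coarse.time, 9))
        for name in "CBMR":
            a = getattr(coarse, name)
            b = getattr(fine, name)[common]
            denom = np.maximum(np.abs(b), np.abs(b).max() * 1e-3)
            assert np.max(np.abs(a - b) / denom) < 1e-4


class TestPopulationSynthesis:
    def make_traj(self):
        return simulate_transient(t_end=48.0, dt=0.1)

    def test_empty_population(self):
        pop = synthesize_population(self.make_traj(), [10, 20], 0, seed=0)
        assert len(pop) == 0

    def test_seed_reproducibility(self):
        traj = self.make_traj()
        a = synthesize_population(traj, [5, 40], 500, seed=42)
        b = synthesize_population(traj, [5, 40], 500, seed=42)
        assert a.equals(b)

    def test_scale_bounds_and_ratio_preservation(self):
        traj = self.make_traj()
        pop = synthesize_population(traj, [10, 30], 2000, seed=1)
        assert ((pop["scale"] >= 10) & (pop["scale"] <= 100)).all()
        states = traj.interp(pop["time"].to_numpy())
        ok = states["R"] > 0
        np.testing.assert_allclose(
            (pop["blue_raw"] / pop["red_raw"]).to_numpy()[ok],
            states["B"][ok] / states["R"][ok], rtol=1e-10)

    def test_out_of_range_times_rejected(self):
        with pytest.raises(ValueError):
            synthesize_population(self.make_traj(), [40, 60], 10)

    def test_empty_times_rejected(self):
        with pytest.raises(ValueError):
            synthesize_population(self.make_traj(), [], 10)


class TestPopulationAngles:
    def test_transient_angles_progress_with_time(self, sim_neg_control):
        """Later sampling windows yield higher median Timer Angle."""
        traj = simulate_transient()
        early = synthesize_population(traj, [2, 6], 2000, seed=3)
        late = synthesize_population(traj, [24, 48], 2000, seed=4)
        ts_early = population_to_angles(early, sim_neg_control)
        ts_late = population_to_angles(late, sim_neg_control)
        assert np.median(ts_late.angles()) > np.median(ts_early.angles())

    def test_early_constant_population_mass_near_zero_degrees(self, sim_neg_control):
        """Shortly after onset blue dominates (kb >> ki): low angles."""
        traj = simulate_constant(100.0, t_end=24.0, dt=0.1)
        pop = synthesize_population(traj, [0.5, 2.0], 2000, seed=6)
        ts = population_to_angles(pop, sim_neg_control)
        assert np.median(ts.angles()) < 30.0

    def test_empty_population(self, sim_neg_control):
        import pandas as pd
        pop = pd.DataFrame({"blue_raw": [], "red_raw": []})
        ts = population_to_angles(pop, sim_neg_control)
        assert ts.n_events == 0


class TestRmse:
    def test_identical_series_zero(self):
        assert rmse([1, 2, 3], [1, 2, 3]) == 0.0

    def test_constant_offset(self):
        assert rmse([10, 20, 30], [12, 22, 32]) == pytest.approx(2.0)

    def test_hand_computed(self):
        assert rmse([10, 20], [13, 16]) == pytest.approx(np.sqrt(12.5))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse([1, 2], [1, 2, 3])
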