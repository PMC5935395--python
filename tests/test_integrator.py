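"""Time stepping: Euler and midpoint accuracy, delay machinery, noise."""

import numpy as np
import pytest

from flock3d import ModelParams, SwarmState, ForceHistory, euler_step, \
    midpoint_step
from flock3d.integrator import run

from conftest import random_state


def single_agent(speed, v0=5.0, **kwargs):
    p = ModelParams(N=1, L=50.0, v0=v0, **kwargs)
    st = SwarmState(0.0, np.array([[25.0, 25, 25]]),
                    np.array([[speed, 0.0, 0.0]]))
    return p, st


class TestEulerStep:
    def test_cruise_at_preferred_speed(self):
        p, st = single_agent(5.0, dt=1e-3)
        new = euler_step(st, p)
        np.testing.assert_allclose(new.velocities, st.velocities)
        np.testing.assert_allclose(
            new.positions, st.positions + st.velocities * p.dt
        )
        assert new.t == pytest.approx(p.dt)

    def test_explicit_update_above_preferred(self):
        p, st = single_agent(10.0, dt=1e-3)
        new = euler_step(st, p)
        assert np.linalg.norm(new.velocities[0]) == pytest.approx(9.995)


class TestSpeedRelaxation:
    """Single-agent speed ODE against v(t) = v0 + (v(0) - v0) exp(-t/tau)."""

    def endpoint_error(self, stepper, dt, T=0.5, v_init=1.0, with_history=False):
        p, st = single_agent(v_init, dt=dt)
        hist = ForceHistory(0, 1) if with_history else None
        n = round(T / dt)
        for _ in range(n):
            st = stepper(st, p) if hist is None else stepper(st, p, hist)
        exact = p.v0 + (v_init - p.v0) * np.exp(-T / p.tau)
        return abs(np.linalg.norm(st.velocities[0]) - exact)

    def test_midpoint_second_order(self):
        e1 = self.endpoint_error(midpoint_step, 0.02)
        e2 = self.endpoint_error(midpoint_step, 0.01)
        assert e1 / e2 == pytest.approx(4.0, rel=0.25)
        assert e2 < 1e-4

    def test_euler_first_order(self):
        e1 = self.endpoint_error(euler_step, 0.02)
        e2 = self.endpoint_error(euler_step, 0.01)
        assert e1 / e2 == pytest.approx(2.0, rel=0.2)

    def test_kernel_run_matches_closed_form(self):
        p, st = single_agent(1.0, dt=1e-3)
        res = run(st, p, T=2.0, record_every=0.5, seed=0)
        speeds = np.linalg.norm(res.final_state.velocities[0])
        exact = p.v0 + (1.0 - p.v0) * np.exp(-2.0 / p.tau)
        assert speeds == pytest.approx(exact, abs=1e-5)


class TestMomentumConservation:
    def test_pure_repulsion_conserves_momentum(self):
        """Central forces: total velocity drift < 1e-8 over 1e4 midpoint steps."""
        p = ModelParams(N=2, L=50.0, tau=1e30)  # huge tau disables propulsion
        st = SwarmState(
            0.0,
            np.array([[24.5, 25.0, 25.0], [25.5, 25.0, 25.0]]),
            np.array([[0.3, 0.1, 0.0], [-0.2, 0.1, 0.05]]),
        )
        p0 = st.velocities.sum(axis=0) * p.mass
        res = run(st, p, T=10.0, record_every=10.0, seed=0)
        p1 = res.final_state.velocities.sum(axis=0) * p.mass
        assert np.all(np.abs(p1 - p0) < 1e-8)


class TestDelayMachinery:
    def test_zero_delay_history_bitwise_identical(self, rng):
        """t_d = 0 with buffers active reproduces the plain path exactly."""
        p = ModelParams(N=20, L=50.0)
        st = random_state(p, rng)
        r_plain = run(st, p, T=2.0, record_every=0.5, seed=3, use_history=False)
        r_hist = run(st, p, T=2.0, record_every=0.5, seed=3, use_history=True)
        assert np.array_equal(r_plain.final_state.positions,
                              r_hist.final_state.positions)
        assert np.array_equal(r_plain.final_state.velocities,
                              r_hist.final_state.velocities)
        assert np.array_equal(r_plain.efficiency, r_hist.efficiency)

    def test_zero_delay_python_path_exact(self, rng):
        p = ModelParams(N=5, L=50.0)
        st = random_state(p, rng)
        hist = ForceHistory(0, p.N)
        a, b = st.copy(), st.copy()
        for _ in range(5):
            a = midpoint_step(a, p)
            b = midpoint_step(b, p, history=hist)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.velocities, b.velocities)

    def test_nonzero_delay_changes_trajectory(self, rng):
        p0 = ModelParams(N=20, L=50.0)
        pd = p0.with_(t_d=10 * p0.dt)
        st = random_state(p0, rng)
        r0 = run(st, p0, T=2.0, record_every=2.0, seed=3)
        rd = run(st, pd, T=2.0, record_every=2.0, seed=3)
        assert not np.allclose(r0.final_state.velocities,
                               rd.final_state.velocities)

    def test_python_and_kernel_delayed_paths_agree(self, rng):
        p = ModelParams(N=8, L=50.0, t_d=3e-3)
        st = random_state(p, rng)
        hist = ForceHistory(p.delay_steps, p.N)
        py = st.copy()
        for _ in range(10):
            py = midpoint_step(py, p, history=hist)
        kr = run(st, p, T=10 * p.dt, record_every=10 * p.dt, seed=0)
        np.testing.assert_allclose(py.positions, kr.final_state.positions,
                                   rtol=0, atol=1e-10)
        np.testing.assert_allclose(py.velocities, kr.final_state.velocities,
                                   rtol=0, atol=1e-10)

    def test_warmup_uses_oldest_record(self):
        """Before the buffer holds t_d of history, lookups clamp to step 0."""
        h = ForceHistory(3, 1)
        records = [np.full((1, 3), float(k)) for k in range(6)]
        out = []
        for rec in records:
            h.store_full(rec)
            out.append(h.delayed_full()[0, 0])
        assert out == [0.0, 0.0, 0.0, 0.0, 1.0, 2.0]


class TestRunContract:
    def test_frame_count_includes_t0(self, rng):
        p = ModelParams(N=3, L=50.0)
        st = random_state(p, rng)
        res = run(st, p, T=10 * p.dt, record_every=p.dt, seed=0)
        assert len(res.times) == 11
        assert res.times[0] == 0.0

    def test_seeded_run_reproducible(self, rng):
        p = ModelParams(N=10, L=50.0, xi=5.0)
        st = random_state(p, rng)
        a = run(st, p, T=1.0, record_every=0.1, seed=7)
        b = run(st, p, T=1.0, record_every=0.1, seed=7)
        assert np.array_equal(a.efficiency, b.efficiency)
        assert np.array_equal(a.final_state.positions, b.final_state.positions)

    def test_different_seed_differs(self, rng):
        p = ModelParams(N=10, L=50.0, xi=5.0)
        st = random_state(p, rng)
        a = run(st, p, T=1.0, record_every=1.0, seed=7)
        b = run(st, p, T=1.0, record_every=1.0, seed=8)
        assert not np.array_equal(a.final_state.velocities,
                                  b.final_state.velocities)

    def test_coincident_agents_abort(self):
        p = ModelParams(N=2, L=50.0)
        st = SwarmState(0.0, np.array([[25.0, 25, 25], [25.0, 25, 25]]),
                        np.zeros((2, 3)))
        with pytest.raises(FloatingPointError):
            run(st, p, T=1.0, record_every=0.1, seed=0)

    def test_bad_record_every_rejected(self, rng):
        p = ModelParams(N=3, L=50.0)
        st = random_state(p, rng)
        with pytest.raises(ValueError):
            run(st, p, T=1.0, record_every=1.5e-3, seed=0)


class TestNoiseDiffusion:
    """Pure-noise limit: velocity variance grows linearly in time, with the
    slope set by the amplitude convention."""

    def variance_slope(self, convention):
        # propulsion and repulsion effectively disabled
        p = ModelParams(N=200, L=50.0, tau=1e30, c=1e-30, xi=1.0,
                        noise_convention=convention)
        pos = np.random.default_rng(0).uniform(0, p.L, (p.N, 3))
        st = SwarmState(0.0, pos, np.zeros((p.N, 3)))
        T = 10.0
        res = run(st, p, T=T, record_every=T, seed=11)
        msq = float(np.mean(np.sum(res.final_state.velocities**2, axis=1)))
        return msq / T

    def test_step_convention_slope(self):
        # slope = xi^2 * dt / m^2 (amplitude xi*dt per step of length dt)
        expected = 1.0**2 * 1e-3
        assert self.variance_slope("step") == pytest.approx(expected, rel=0.15)

    def test_sqrt_convention_slope(self):
        # slope = xi^2 / m^2, independent of dt
        assert self.variance_slope("sqrt") == pytest.approx(1.0, rel=0.15)


class TestSnapshotRun:
    def test_frames_align_with_plain_run(self, rng):
        from flock3d.integrator import run_with_snapshots

        p = ModelParams(N=10, L=50.0)
        st = random_state(p, rng)
        plain = run(st, p, T=1.0, record_every=0.25, seed=0)
        res, frames = run_with_snapshots(st, p, T=1.0, snapshot_every=0.25,
                                         seed=0)
        assert len(frames) == 5
        # deterministic (xi = 0): final states coincide exactly
        assert np.array_equal(res.final_state.positions,
                              plain.final_state.positions)
        np.testing.assert_allclose(res.efficiency, plain.efficiency)

    def test_delayed_run_rejected(self, rng):
        from flock3d.integrator import run_with_snapshots

        p = ModelParams(N=5, L=50.0, t_d=2e-3)
        st = random_state(p, rng)
        with pytest.raises(ValueError, match="t_d"):
            run_with_snapshots(st, p, T=1.0, snapshot_every=0.5)
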