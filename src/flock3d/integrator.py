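"""Time stepping: forward Euler and explicit midpoint, with optional noise
injection and delayed forces.

Two paths are provided.  :func:`euler_step` and :func:`midpoint_step` are
transparent single-step reference implementations built on
:func:`flock3d.model.net_forces`; they define the semantics and are what
the unit tests exercise against closed forms.  :func:`run` drives the
compiled kernel in :mod:`flock3d._kernels` for long trajectories,
recording the efficiency (and any user observables) at a fixed cadence.

Delayed interactions replace the deterministic forces on the right-hand
side by the same forces evaluated ``t_d`` earlier; the delay is an integer
number of steps and is served from per-evaluation-time ring buffers
(:class:`ForceHistory`).  Before the history holds ``t_d`` worth of
records, the oldest available record is used (clamped lookup), which
avoids a discontinuous force onset at the start of a run.  Noise is drawn
fresh at application time and is never delayed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

import numpy as np

from . import _kernels
from .model import ModelParams, SwarmState, net_forces, noise_impulse
from .observables import EfficiencySeries, efficiency
from .space import neighbor_pairs, wrap_position

__all__ = ["ForceHistory", "euler_step", "midpoint_step", "run", "RunResult"]

logger = logging.getLogger(__name__)


class ForceHistory:
    """Ring buffers of past full-step and half-step force evaluations.

    Records are indexed by the global step count at which the force was
    evaluated.  A lookup at step ``k`` returns the record stored at step
    ``k - delay_steps``, clamped to the oldest record while the buffer is
    still warming up.
    """

    def __init__(self, delay_steps: int, N: int):
        if delay_steps < 0:
            raise ValueError("delay_steps must be >= 0")
        self.delay_steps = delay_steps
        cap = delay_steps + 1
        self.full_buf = np.zeros((cap, N, 3))
        self.half_buf = np.zeros((cap, N, 3))
        self._k_full = 0  # next global step index to store
        self._k_half = 0

    @property
    def capacity(self) -> int:
        return self.delay_steps + 1

    def store_full(self, F: np.ndarray) -> None:
        self.full_buf[self._k_full % self.capacity] = F
        self._k_full += 1

    def store_half(self, F: np.ndarray) -> None:
        self.half_buf[self._k_half % self.capacity] = F
        self._k_half += 1

    def delayed_full(self) -> np.ndarray:
        """Record for the step just stored (current step), delayed and clamped."""
        k = self._k_full - 1
        if k < 0:
            raise RuntimeError("no full-step force stored yet")
        return self.full_buf[max(0, k - self.delay_steps) % self.capacity]

    def delayed_half(self) -> np.ndarray:
        k = self._k_half - 1
        if k < 0:
            raise RuntimeError("no half-step force stored yet")
        return self.half_buf[max(0, k - self.delay_steps) % self.capacity]


def _check_finite(F: np.ndarray, t: float) -> None:
    if not np.isfinite(F).all():
        raise FloatingPointError(
            f"non-finite force at t={t:g} (agent overlap or blow-up)"
        )


def euler_step(
    state: SwarmState,
    params: ModelParams,
    rng: Optional[np.random.Generator] = None,
) -> SwarmState:
    """One forward-Euler step: v += (F/m) dt (+ noise), r += v_old dt, wrapped."""
    F = net_forces(state, neighbor_pairs(state, params), params)
    _check_finite(F, state.t)
    new_v = state.velocities + (F / params.mass) * params.dt
    if params.xi > 0:
        if rng is None:
            raise ValueError("xi > 0 requires an rng")
        for i in range(params.N):
            new_v[i] += noise_impulse(
                params.xi, params.dt, params.mass, rng, params.noise_convention
            )
    new_r = wrap_position(state.positions + state.velocities * params.dt, params.L)
    return SwarmState(state.t + params.dt, new_r, new_v)


def midpoint_step(
    state: SwarmState,
    params: ModelParams,
    history: Optional[ForceHistory] = None,
    rng: Optional[np.random.Generator] = None,
) -> SwarmState:
    """One explicit-midpoint step, optionally with delayed forces.

    Forces ``F1`` are evaluated at the current state and used (possibly
    delayed through ``history``) to build the half-step state at
    ``t + dt/2``; forces ``F2`` evaluated there advance the velocity over
    the full step, while the position advances with the half-step
    velocity.  Freshly evaluated forces are always appended to the
    history, so a zero-delay history reproduces the plain path exactly.
    """
    dt, m = params.dt, params.mass
    if params.delay_steps > 0 and history is None:
        raise ValueError("t_d > 0 requires a ForceHistory")
    if params.xi > 0 and rng is None:
        raise ValueError("xi > 0 requires an rng")

    F1 = net_forces(state, neighbor_pairs(state, params), params)
    _check_finite(F1, state.t)
    if history is not None:
        history.store_full(F1)
        F1 = history.delayed_full()
    vel_half = state.velocities + (F1 / m) * (0.5 * dt)
    pos_half = wrap_position(state.positions + state.velocities * (0.5 * dt), params.L)
    if params.xi > 0:
        for i in range(params.N):
            vel_half[i] += noise_impulse(
                params.xi, 0.5 * dt, m, rng, params.noise_convention
            )
    half_state = SwarmState(state.t + 0.5 * dt, pos_half, vel_half)
    F2 = net_forces(half_state, neighbor_pairs(half_state, params), params)
    _check_finite(F2, half_state.t)
    if history is not None:
        history.store_half(F2)
        F2 = history.delayed_half()
    new_v = state.velocities + (F2 / m) * dt
    if params.xi > 0:
        for i in range(params.N):
            new_v[i] += noise_impulse(params.xi, dt, m, rng, params.noise_convention)
    new_r = wrap_position(state.positions + vel_half * dt, params.L)
    return SwarmState(state.t + dt, new_r, new_v)


@dataclass
class RunResult:
    """Outcome of :func:`run`: recorded observables plus the final state."""

    series: EfficiencySeries
    final_state: SwarmState
    params: ModelParams
    seed: int
    observables: dict = field(default_factory=dict)  # name -> np.ndarray over records

    @property
    def times(self) -> np.ndarray:
        return self.series.times

    @property
    def efficiency(self) -> np.ndarray:
        return self.series.values


def run(
    state: SwarmState,
    params: ModelParams,
    T: float,
    record_every: float,
    observers: Optional[Mapping[str, Callable[[SwarmState], float]]] = None,
    seed: int = 0,
    use_history: Optional[bool] = None,
) -> RunResult:
    """Integrate for a duration ``T`` with the compiled midpoint kernel.

    The efficiency (and each observer) is recorded at ``t = 0`` and then
    every ``record_every`` seconds; ``record_every`` must be a multiple of
    ``dt``.  The noise stream is fully determined by ``seed`` (and the
    recording cadence, which sets the kernel chunking): the same call
    repeated yields an identical trajectory.  ``use_history`` forces the
    delay machinery on or off (default: on iff ``t_d > 0``); at ``t_d = 0``
    both paths are bitwise identical.
    """
    if T <= 0:
        raise ValueError("T must be > 0")
    dt = params.dt
    spr = round(record_every / dt)
    if spr < 1 or abs(record_every - spr * dt) > 1e-9 * dt:
        raise ValueError("record_every must be a positive multiple of dt")
    n_steps = round(T / dt)
    if use_history is None:
        use_history = params.delay_steps > 0
    if params.delay_steps > 0 and not use_history:
        raise ValueError("t_d > 0 requires the delay machinery")
    state = state.copy()
    state.validate(params)

    cap = params.delay_steps + 1
    full_buf = np.zeros((cap, params.N, 3))
    half_buf = np.zeros((cap, params.N, 3))
    ss = np.random.SeedSequence(seed)
    chunk_seeds = ss.generate_state(max(1, -(-n_steps // spr)), dtype=np.uint32)

    times = [state.t]
    values = [efficiency(state, params)]
    obs_series: dict = {name: [fn(state)] for name in (observers or {})
                        for fn in [observers[name]]}

    sqrt_noise = params.noise_convention == "sqrt"
    k = 0
    chunk = 0
    t0 = state.t
    while k < n_steps:
        n = min(spr, n_steps - k)
        _kernels.midpoint_chunk(
            state.positions,
            state.velocities,
            params.L,
            params.v0,
            params.tau,
            params.mass,
            params.c,
            params.R,
            params.xi,
            dt,
            n,
            sqrt_noise,
            use_history,
            params.delay_steps,
            full_buf,
            half_buf,
            k,
            np.int64(chunk_seeds[chunk] & 0x7FFFFFFF),
        )
        k += n
        chunk += 1
        state.t = t0 + k * dt
        if not (np.isfinite(state.positions).all() and np.isfinite(state.velocities).all()):
            raise FloatingPointError(
                f"non-finite state at step {k} (t={state.t:g}); aborting"
            )
        times.append(state.t)
        values.append(efficiency(state, params))
        for name, fn in (observers or {}).items():
            obs_series[name].append(fn(state))

    series = EfficiencySeries(np.asarray(times), np.asarray(values))
    obs = {name: np.asarray(v) for name, v in obs_series.items()}
    return RunResult(series=series, final_state=state, params=params, seed=seed,
                     observables=obs)


def run_with_snapshots(
    state: SwarmState,
    params: ModelParams,
    T: float,
    snapshot_every: float,
    seed: int = 0,
    use_history: Optional[bool] = None,
):
    """Like :func:`run`, but also keep a full state snapshot at every
    recording time (including t = 0), e.g. for XYZ trajectory export.

    Returns ``(RunResult, frames)`` where ``frames`` is a list of
    :class:`SwarmState`.  Delayed runs are not supported here: the force
    history would be re-warmed at every snapshot boundary.
    """
    if params.delay_steps > 0:
        raise ValueError("run_with_snapshots requires t_d = 0")
    frames = [state.copy()]

    times = [state.t]
    values = [efficiency(state, params)]
    current = state
    n_snaps = round(T / snapshot_every)
    if abs(T - n_snaps * snapshot_every) > 1e-9 * params.dt or n_snaps < 1:
        raise ValueError("T must be a positive multiple of snapshot_every")
    for k in range(n_snaps):
        res = run(current, params, T=snapshot_every,
                  record_every=snapshot_every, seed=seed + k,
                  use_history=use_history)
        current = res.final_state
        current.t = state.t + (k + 1) * snapshot_every
        frames.append(current.copy())
        times.append(current.t)
        values.append(res.efficiency[-1])
    series = EfficiencySeries(np.asarray(times), np.asarray(values))
    result = RunResult(series=series, final_state=current, params=params,
                       seed=seed)
    return result, frames
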