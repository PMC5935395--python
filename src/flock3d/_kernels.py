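"""Compiled inner loops (numba) for the many-agent and two-agent dynamics.

These kernels mirror the pure-Python reference path in
:mod:`flock3d.model` / :mod:`flock3d.integrator` exactly in model content;
they exist only to make desk-scale ensembles (10^7 steps and more)
practical on one CPU.  Pair search inside the kernel is an all-pairs
minimum-image scan with the cutoff applied per pair; at the agent counts
used here (N <= a few hundred, 3x3x3 .. 5x5x5 grid cells) this touches the
same pairs as the cell grid and is equally fast.
"""

import numba as nb
import numpy as np

__all__ = ["total_forces", "midpoint_chunk", "euler_chunk", "encounter_euler"]


@nb.njit(cache=True, error_model="numpy")
def total_forces(pos, vel, L, v0, tau, mass, c, R, F):
    """Propulsion + minimum-image pairwise repulsion with cutoff, into F."""
    N = pos.shape[0]
    ktau = mass / tau
    for i in range(N):
        vx = vel[i, 0]
        vy = vel[i, 1]
        vz = vel[i, 2]
        s = np.sqrt(vx * vx + vy * vy + vz * vz)
        if s > 0.0:
            f = ktau * (v0 - s) / s
            F[i, 0] = f * vx
            F[i, 1] = f * vy
            F[i, 2] = f * vz
        else:
            F[i, 0] = 0.0
            F[i, 1] = 0.0
            F[i, 2] = 0.0
    half = 0.5 * L
    R2 = R * R
    for i in range(N):
        xi_ = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        for j in range(i + 1, N):
            dx = xi_ - pos[j, 0]
            dy = yi - pos[j, 1]
            dz = zi - pos[j, 2]
            if dx >= half:
                dx -= L
            elif dx < -half:
                dx += L
            if dy >= half:
                dy -= L
            elif dy < -half:
                dy += L
            if dz >= half:
                dz -= L
            elif dz < -half:
                dz += L
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < R2:
                w = c / (r2 * np.sqrt(r2))
                fx = w * dx
                fy = w * dy
                fz = w * dz
                F[i, 0] += fx
                F[i, 1] += fy
                F[i, 2] += fz
                F[j, 0] -= fx
                F[j, 1] -= fy
                F[j, 2] -= fz
    return F


@nb.njit(cache=True, error_model="numpy")
def _wrap_inplace(pos, L):
    N = pos.shape[0]
    for i in range(N):
        for a in range(3):
            x = pos[i, a] - L * np.floor(pos[i, a] / L)
            if x >= L:
                x -= L
            pos[i, a] = x


@nb.njit(cache=True, error_model="numpy")
def _add_noise(vel, amp):
    """Add an isotropic impulse of fixed magnitude ``amp`` to every agent."""
    N = vel.shape[0]
    for i in range(N):
        gx = np.random.standard_normal()
        gy = np.random.standard_normal()
        gz = np.random.standard_normal()
        g = np.sqrt(gx * gx + gy * gy + gz * gz)
        if g > 0.0:
            s = amp / g
            vel[i, 0] += s * gx
            vel[i, 1] += s * gy
            vel[i, 2] += s * gz


@nb.njit(cache=True, error_model="numpy")
def midpoint_chunk(
    pos,
    vel,
    L,
    v0,
    tau,
    mass,
    c,
    R,
    xi,
    dt,
    n_steps,
    sqrt_noise,
    use_history,
    delay_steps,
    full_buf,
    half_buf,
    k0,
    seed,
):
    """Advance ``n_steps`` explicit-midpoint steps in place.

    ``full_buf`` / ``half_buf`` are ring buffers of shape
    ``(delay_steps + 1, N, 3)`` holding past full-step and half-step force
    evaluations; when ``use_history`` the forces applied at global step
    ``k`` are the records from step ``max(0, k - delay_steps)`` (clamped
    during warm-up), while freshly evaluated forces are always appended.
    With ``delay_steps == 0`` the stored record is the one just computed,
    so the history path reproduces the plain path bit for bit.

    ``k0`` is the global index of the first step of this chunk; ``seed``
    seeds the chunk-local noise stream (unused when ``xi == 0``).
    """
    N = pos.shape[0]
    if xi > 0.0:
        np.random.seed(seed)
        if sqrt_noise:
            amp_half = xi * np.sqrt(0.5 * dt) / mass
            amp_full = xi * np.sqrt(dt) / mass
        else:
            amp_half = xi * (0.5 * dt) / mass
            amp_full = xi * dt / mass
    else:
        amp_half = 0.0
        amp_full = 0.0
    cap = delay_steps + 1
    F1 = np.empty((N, 3))
    F2 = np.empty((N, 3))
    pos_half = np.empty((N, 3))
    vel_half = np.empty((N, 3))
    for s in range(n_steps):
        k = k0 + s
        total_forces(pos, vel, L, v0, tau, mass, c, R, F1)
        if use_history:
            full_buf[k % cap] = F1
            F1u = full_buf[max(0, k - delay_steps) % cap]
        else:
            F1u = F1
        hdt = 0.5 * dt
        for i in range(N):
            for a in range(3):
                vel_half[i, a] = vel[i, a] + (F1u[i, a] / mass) * hdt
                pos_half[i, a] = pos[i, a] + vel[i, a] * hdt
        _wrap_inplace(pos_half, L)
        if amp_half > 0.0:
            _add_noise(vel_half, amp_half)
        total_forces(pos_half, vel_half, L, v0, tau, mass, c, R, F2)
        if use_history:
            half_buf[k % cap] = F2
            F2u = half_buf[max(0, k - delay_steps) % cap]
        else:
            F2u = F2
        for i in range(N):
            for a in range(3):
                pos[i, a] = pos[i, a] + vel_half[i, a] * dt
                vel[i, a] = vel[i, a] + (F2u[i, a] / mass) * dt
        _wrap_inplace(pos, L)
        if amp_full > 0.0:
            _add_noise(vel, amp_full)
    return n_steps


@nb.njit(cache=True, error_model="numpy")
def euler_chunk(pos, vel, L, v0, tau, mass, c, R, xi, dt, n_steps, sqrt_noise, seed):
    """Advance ``n_steps`` forward-Euler steps in place (no delay)."""
    N = pos.shape[0]
    if xi > 0.0:
        np.random.seed(seed)
        amp = xi * np.sqrt(dt) / mass if sqrt_noise else xi * dt / mass
    else:
        amp = 0.0
    F = np.empty((N, 3))
    for _ in range(n_steps):
        total_forces(pos, vel, L, v0, tau, mass, c, R, F)
        for i in range(N):
            for a in range(3):
                p = pos[i, a] + vel[i, a] * dt
                vel[i, a] = vel[i, a] + (F[i, a] / mass) * dt
                pos[i, a] = p
        _wrap_inplace(pos, L)
        if amp > 0.0:
            _add_noise(vel, amp)
    return n_steps


@nb.njit(cache=True, error_model="numpy")
def encounter_euler(state, D_stop, v0, tau, mass, c, dt, max_steps):
    """Two-agent open-space forward-Euler integration (no cutoff, no box).

    ``state`` is a flat 12-vector ``(p1, v1, p2, v2)`` advanced in place,
    so the caller can record or resume mid-encounter.  Integration stops
    when the distance projected onto the xy plane (the plane-parallel
    "horizontal" distance) reaches ``D_stop``, or after ``max_steps``.

    Returns ``(steps_taken, closest_approach_seen, finished)``.
    """
    p1x, p1y, p1z = state[0], state[1], state[2]
    v1x, v1y, v1z = state[3], state[4], state[5]
    p2x, p2y, p2z = state[6], state[7], state[8]
    v2x, v2y, v2z = state[9], state[10], state[11]
    ktau = mass / tau
    dx0 = p1x - p2x
    dy0 = p1y - p2y
    dz0 = p1z - p2z
    closest = np.sqrt(dx0 * dx0 + dy0 * dy0 + dz0 * dz0)
    stop2 = D_stop * D_stop
    steps = 0
    finished = False
    while steps < max_steps:
        hx = p1x - p2x
        hy = p1y - p2y
        if hx * hx + hy * hy >= stop2:
            finished = True
            break
        dx = p1x - p2x
        dy = p1y - p2y
        dz = p1z - p2z
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        if r < closest:
            closest = r
        w = c / (r2 * r)
        # propulsion agent 1
        s1 = np.sqrt(v1x * v1x + v1y * v1y + v1z * v1z)
        f1 = ktau * (v0 - s1) / s1 if s1 > 0.0 else 0.0
        F1x = f1 * v1x + w * dx
        F1y = f1 * v1y + w * dy
        F1z = f1 * v1z + w * dz
        s2 = np.sqrt(v2x * v2x + v2y * v2y + v2z * v2z)
        f2 = ktau * (v0 - s2) / s2 if s2 > 0.0 else 0.0
        F2x = f2 * v2x - w * dx
        F2y = f2 * v2y - w * dy
        F2z = f2 * v2z - w * dz
        p1x += v1x * dt
        p1y += v1y * dt
        p1z += v1z * dt
        p2x += v2x * dt
        p2y += v2y * dt
        p2z += v2z * dt
        v1x += (F1x / mass) * dt
        v1y += (F1y / mass) * dt
        v1z += (F1z / mass) * dt
        v2x += (F2x / mass) * dt
        v2y += (F2y / mass) * dt
        v2z += (F2z / mass) * dt
        steps += 1
    state[0], state[1], state[2] = p1x, p1y, p1z
    state[3], state[4], state[5] = v1x, v1y, v1z
    state[6], state[7], state[8] = p2x, p2y, p2z
    state[9], state[10], state[11] = v2x, v2y, v2z
    return steps, closest, finished
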