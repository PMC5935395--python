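"""Core model definition: parameters, swarm state, and the forces of the
equations of motion.

Each of the ``N`` agents carries a position ``r_i`` and a velocity ``v_i``
in a cubic periodic box of side ``L``.  The deterministic right-hand side
of the equations of motion has two terms:

* **self-propulsion** — the agent relaxes its speed toward a preferred
  value ``v0`` with characteristic time ``tau``, along its own heading:
  ``F_prop = (m/tau) * (v0 - |v|) * v/|v|``;
* **radial repulsion** — every pair closer than the cutoff ``R`` repels
  with magnitude ``c / r**2`` along the line of centres.

Noise, when enabled, enters as an isotropic random impulse applied by the
integrator (see :mod:`flock3d.integrator`); it is never routed through the
delay buffers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ModelParams",
    "SwarmState",
    "propulsion_force",
    "repulsion_force",
    "noise_impulse",
    "net_forces",
]

#: Noise-amplitude conventions for an impulse spanning ``interval`` seconds.
#: "step"  — velocity increment of magnitude xi * interval / mass (a constant
#:           force of magnitude xi held over the interval; the convention the
#:           reported noise thresholds are calibrated to).
#: "sqrt"  — diffusive scaling xi * sqrt(interval) / mass (interval-
#:           independent velocity diffusion; provided for sensitivity checks).
NOISE_CONVENTIONS = ("step", "sqrt")


@dataclass(frozen=True)
class ModelParams:
    """Physical and numerical constants of the flocking model (SI units).

    Parameters
    ----------
    N : int
        Number of agents.
    L : float
        Side of the cubic periodic box (m).  Must satisfy
        ``floor(L / R) >= 3`` so that the 27-cell neighbour search of the
        cell grid is exhaustive.
    v0 : float
        Preferred speed (m/s).
    tau : float
        Speed relaxation time (s).
    mass : float
        Agent mass (kg).
    c : float
        Repulsion constant (N m^2); pair force magnitude is ``c / r**2``.
    R : float
        Interaction cutoff (m): pairs at minimum-image distance >= R do
        not interact.
    xi : float
        Noise amplitude (N); zero disables noise.
    dt : float
        Integration time step (s).
    t_d : float
        Interaction delay (s); must be an integer multiple of ``dt``.
    noise_convention : str
        Time-scaling of the noise impulse, one of ``NOISE_CONVENTIONS``.
    """

    N: int
    L: float = 50.0
    v0: float = 5.0
    tau: float = 1.0
    mass: float = 1.0
    c: float = 1.0
    R: float = 10.0
    xi: float = 0.0
    dt: float = 1e-3
    t_d: float = 0.0
    noise_convention: str = "step"

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        for name in ("L", "v0", "tau", "mass", "c", "R", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.xi < 0:
            raise ValueError(f"xi must be >= 0, got {self.xi}")
        if self.t_d < 0:
            raise ValueError(f"t_d must be >= 0, got {self.t_d}")
        if math.floor(self.L / self.R) < 3:
            raise ValueError(
                f"floor(L/R) must be >= 3 for an exhaustive 27-cell search; "
                f"got L={self.L}, R={self.R}"
            )
        k = round(self.t_d / self.dt)
        if abs(self.t_d - k * self.dt) > 1e-9 * self.dt:
            raise ValueError(
                f"t_d={self.t_d} must be an integer multiple of dt={self.dt}"
            )
        if self.noise_convention not in NOISE_CONVENTIONS:
            raise ValueError(
                f"noise_convention must be one of {NOISE_CONVENTIONS}, "
                f"got {self.noise_convention!r}"
            )

    @property
    def delay_steps(self) -> int:
        """Delay expressed in integration steps, ``t_d / dt``."""
        return round(self.t_d / self.dt)

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class SwarmState:
    """Snapshot of the swarm: time plus per-agent positions and velocities.

    ``positions`` and ``velocities`` are ``(N, 3)`` float arrays; position
    components live in ``[0, L)``.
    """

    t: float
    positions: np.ndarray
    velocities: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        if self.positions.shape != self.velocities.shape or self.positions.ndim != 2 \
                or self.positions.shape[1] != 3:
            raise ValueError(
                f"positions and velocities must both be (N, 3); got "
                f"{self.positions.shape} and {self.velocities.shape}"
            )
        if not (np.isfinite(self.positions).all() and np.isfinite(self.velocities).all()):
            raise ValueError("non-finite position or velocity")

    @property
    def N(self) -> int:
        return self.positions.shape[0]

    def validate(self, params: ModelParams) -> None:
        """Check consistency with ``params`` (agent count, box membership)."""
        if self.N != params.N:
            raise ValueError(f"state has {self.N} agents, params expect {params.N}")
        if (self.positions < 0).any() or (self.positions >= params.L).any():
            raise ValueError("position component outside [0, L)")

    def copy(self) -> "SwarmState":
        return SwarmState(self.t, self.positions.copy(), self.velocities.copy())


def propulsion_force(v: np.ndarray, params: ModelParams) -> np.ndarray:
    """Self-propulsion force ``(m/tau) * (v0 - |v|) * v/|v|`` for one agent.

    Parallel to ``v`` below the preferred speed, antiparallel above it,
    zero at ``|v| = v0``.  A zero velocity has no defined heading; the
    force is then the zero vector (isotropy-preserving convention for a
    measure-zero event).
    """
    v = np.asarray(v, dtype=np.float64)
    speed = float(np.linalg.norm(v))
    if speed == 0.0:
        return np.zeros(3)
    return (params.mass / params.tau) * (params.v0 - speed) * (v / speed)


def repulsion_force(
    disp: np.ndarray, params: ModelParams, apply_cutoff: bool = True
) -> np.ndarray:
    """Repulsion on agent *i* given displacement ``disp = r_i - r_j``.

    Magnitude ``c / r**2`` directed along ``disp`` (pushing *i* away from
    *j*); exactly zero when ``apply_cutoff`` and ``r >= R``.  Coincident
    agents (``r == 0``) are a hard error: the force direction is undefined
    and the initializer forbids the configuration.
    """
    disp = np.asarray(disp, dtype=np.float64)
    r = float(np.linalg.norm(disp))
    if r == 0.0:
        raise FloatingPointError("coincident agents: repulsion force undefined at r=0")
    if apply_cutoff and r >= params.R:
        return np.zeros(3)
    return (params.c / r**3) * disp


def noise_impulse(
    xi: float,
    interval: float,
    mass: float,
    rng: np.random.Generator,
    convention: str = "step",
) -> np.ndarray:
    """Random velocity increment for a noise force acting over ``interval``.

    The direction is uniform on the unit sphere, independent across calls
    and agents; the magnitude is ``xi * interval / mass`` under the "step"
    convention (constant force over the interval) or
    ``xi * sqrt(interval) / mass`` under the diffusive "sqrt" convention.
    Returns the zero vector when ``xi == 0`` without consuming randomness.
    """
    if xi < 0:
        raise ValueError("xi must be >= 0")
    if interval <= 0:
        raise ValueError("interval must be > 0")
    if xi == 0.0:
        return np.zeros(3)
    if convention == "step":
        mag = xi * interval / mass
    elif convention == "sqrt":
        mag = xi * math.sqrt(interval) / mass
    else:
        raise ValueError(f"unknown noise convention {convention!r}")
    g = rng.standard_normal(3)
    n = np.linalg.norm(g)
    while n == 0.0:  # pragma: no cover - probability zero
        g = rng.standard_normal(3)
        n = np.linalg.norm(g)
    return (mag / n) * g


def net_forces(state: SwarmState, pairs, params: ModelParams) -> np.ndarray:
    """Total deterministic force on every agent.

    ``pairs`` is an iterable of ``(i, j, disp, dist)`` records — exactly
    the unordered pairs at minimum-image distance below the cutoff, as
    produced by :func:`flock3d.space.neighbor_pairs`; ``disp`` is the
    minimum-image displacement ``r_i - r_j``.  Repulsion is accumulated
    antisymmetrically, so its sum over all agents is the zero vector.
    Noise is not included here (the integrator applies it separately).
    """
    F = np.empty_like(state.velocities)
    for i in range(state.N):
        F[i] = propulsion_force(state.velocities[i], params)
    for (i, j, disp, dist) in pairs:
        if dist == 0.0:
            raise FloatingPointError(f"coincident agents {i} and {j}")
        f = (params.c / dist**3) * np.asarray(disp, dtype=np.float64)
        F[i] += f
        F[j] -= f
    return F
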