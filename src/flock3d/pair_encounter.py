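"""The symmetric two-agent scattering experiment.

Two identical agents move so that their velocity vectors stay mirror
images of each other in the plane x = 0 containing their centre of mass.
Their initial velocities lie in two parallel planes a distance ``d``
apart; viewed along the plane normal (the z axis) the agents start a
projected distance D0 = 1000 m apart with an angle ``phi`` between their
velocities.  The encounter is integrated with forward Euler — no noise,
no interaction cutoff, no periodic box — until the projected distance
reaches D_stop = 1100 m.

The observable is the change of the total momentum magnitude,
``delta_I = |p1 + p2|_final - |p1 + p2|_initial``: positive delta_I means
the pair departs more aligned than it arrived.  The initial angle above
which delta_I turns positive (the alignment threshold) lies between 40
and 50 degrees, weakly depending on d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from . import _kernels

__all__ = [
    "EncounterConfig",
    "EncounterResult",
    "setup_encounter",
    "run_encounter",
    "threshold_angle",
    "dt_convergence",
    "scan_map",
]


@dataclass(frozen=True)
class EncounterConfig:
    """Geometry and numerics of one symmetric encounter.

    ``phi`` is in degrees; ``d`` is the separation of the two velocity
    planes (m).  The cutoff is disabled: over distances up to D_stop the
    inverse-square tail is weak but nonzero, and the encounter geometry
    never enters a periodic box.
    """

    d: float
    phi: float
    D0: float = 1000.0
    D_stop: float = 1100.0
    v0: float = 1.0
    tau: float = 1.0
    mass: float = 1.0
    c: float = 1.0
    dt: float = 1e-5
    max_time: float = 50_000.0  # step budget = max_time / dt

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("d must be > 0")
        if not 0.0 < self.phi <= 180.0:
            raise ValueError(
                "phi must be in (0, 180] degrees; phi = 0 never converges"
            )
        if self.D_stop <= self.D0:
            raise ValueError("D_stop must exceed D0")
        for name in ("v0", "tau", "mass", "c", "dt", "max_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class EncounterResult:
    """Outcome of one encounter."""

    delta_I: float  # change of |p1 + p2| (kg m/s)
    steps: int
    closest_approach: float  # minimum 3-D distance reached (m)
    initial_momentum: float
    final_momentum: float


def setup_encounter(config: EncounterConfig) -> np.ndarray:
    """Initial flat state vector (p1, v1, p2, v2) of the mirror pair.

    Agent 1: position (-D0/2, 0, +d/2), velocity
    v0 (sin(phi/2), cos(phi/2), 0); agent 2 is the reflection through the
    x = 0 plane.  The projected (xy) separation is D0 and the angle
    between the velocities is phi.
    """
    h = math.radians(config.phi) / 2.0
    v0 = config.v0
    state = np.array(
        [
            -0.5 * config.D0, 0.0, 0.5 * config.d,
            v0 * math.sin(h), v0 * math.cos(h), 0.0,
            0.5 * config.D0, 0.0, -0.5 * config.d,
            -v0 * math.sin(h), v0 * math.cos(h), 0.0,
        ]
    )
    return state


def total_momentum(state: np.ndarray, mass: float) -> np.ndarray:
    return mass * (state[3:6] + state[9:12])


def run_encounter(
    config: EncounterConfig,
    record_every_steps: Optional[int] = None,
) -> EncounterResult | Tuple[EncounterResult, np.ndarray]:
    """Integrate one encounter to the stopping distance.

    With ``record_every_steps`` set, also returns the array of recorded
    12-component states (for symmetry checks and trajectory plots).
    """
    state = setup_encounter(config)
    I0 = float(np.linalg.norm(total_momentum(state, config.mass)))
    max_steps = int(round(config.max_time / config.dt))
    closest = math.sqrt(config.D0**2 + config.d**2)
    steps = 0
    frames = [state.copy()] if record_every_steps else None
    chunk = record_every_steps if record_every_steps else max_steps
    finished = False
    while steps < max_steps and not finished:
        n, c_seen, finished = _kernels.encounter_euler(
            state,
            config.D_stop,
            config.v0,
            config.tau,
            config.mass,
            config.c,
            config.dt,
            min(chunk, max_steps - steps),
        )
        steps += n
        closest = min(closest, c_seen)
        if frames is not None:
            frames.append(state.copy())
    if not finished:
        raise RuntimeError(
            f"encounter did not reach D_stop={config.D_stop} within "
            f"{max_steps} steps (d={config.d}, phi={config.phi})"
        )
    If = float(np.linalg.norm(total_momentum(state, config.mass)))
    result = EncounterResult(
        delta_I=If - I0,
        steps=steps,
        closest_approach=closest,
        initial_momentum=I0,
        final_momentum=If,
    )
    if frames is not None:
        return result, np.asarray(frames)
    return result


def delta_I(d: float, phi: float, dt: float = 1e-5, **kwargs) -> float:
    """Convenience: delta_I for one (d, phi) point."""
    cfg = EncounterConfig(d=d, phi=phi, dt=dt, **kwargs)
    return run_encounter(cfg).delta_I


def threshold_angle(
    d: float,
    phi_lo: float = 30.0,
    phi_hi: float = 60.0,
    resolution: float = 0.5,
    dt: float = 1e-4,
    coarse_step: float = 5.0,
    **kwargs,
) -> float:
    """Angle at which delta_I changes sign, by coarse scan plus bisection.

    Raises (reporting delta_I at both ends) when the bracket contains no
    sign change.
    """
    lo, hi = phi_lo, phi_hi
    f_lo = delta_I(d, lo, dt=dt, **kwargs)
    f_hi = delta_I(d, hi, dt=dt, **kwargs)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if np.sign(f_lo) == np.sign(f_hi):
        # coarse scan for an interior bracket
        grid = np.arange(lo + coarse_step, hi, coarse_step)
        found = False
        prev_phi, prev_f = lo, f_lo
        for phi in grid:
            f = delta_I(d, float(phi), dt=dt, **kwargs)
            if np.sign(f) != np.sign(prev_f):
                lo, f_lo, hi, f_hi = prev_phi, prev_f, float(phi), f
                found = True
                break
            prev_phi, prev_f = float(phi), f
        if not found:
            raise ValueError(
                f"no sign change of delta_I in [{phi_lo}, {phi_hi}] deg at "
                f"d={d}: delta_I({phi_lo})={f_lo:.3g}, "
                f"delta_I({phi_hi})={f_hi:.3g}"
            )
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        f_mid = delta_I(d, mid, dt=dt, **kwargs)
        if f_mid == 0.0:
            return mid
        if np.sign(f_mid) == np.sign(f_lo):
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
    return 0.5 * (lo + hi)


def dt_convergence(
    points: Sequence[Tuple[float, float]],
    dt_coarse: float = 1e-4,
    dt_fine: float = 1e-5,
    **kwargs,
) -> float:
    """Max |delta_I(dt_coarse) - delta_I(dt_fine)| over the given (d, phi)."""
    if len(points) == 0:
        raise ValueError("need at least one (d, phi) point")
    worst = 0.0
    for d, phi in points:
        a = delta_I(d, phi, dt=dt_coarse, **kwargs)
        b = delta_I(d, phi, dt=dt_fine, **kwargs)
        worst = max(worst, abs(a - b))
    return worst


def scan_map(
    d_values: Sequence[float],
    phi_values: Sequence[float],
    dt: float = 1e-4,
    **kwargs,
):
    """delta_I over a (d, phi) grid, as a tidy DataFrame
    (d, phi, delta_I, closest_approach, steps)."""
    import pandas as pd

    rows = []
    for d in d_values:
        for phi in phi_values:
            res = run_encounter(EncounterConfig(d=d, phi=phi, dt=dt, **kwargs))
            rows.append(
                {
                    "d": d,
                    "phi": phi,
                    "delta_I": res.delta_I,
                    "closest_approach": res.closest_approach,
                    "steps": res.steps,
                }
            )
    return pd.DataFrame(rows)
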