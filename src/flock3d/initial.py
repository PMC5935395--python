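"""Initial conditions: random placement with a minimum pair distance, and
the disordered / ordered velocity initialisations.

Agents are placed uniformly in the periodic box by sequential rejection
sampling, with no pair allowed closer (minimum-image) than
``0.6 L N^(-1/3)`` — roughly 0.6 of the mean inter-agent spacing, a loose
packing that the sampler fills easily.  Speeds always start exactly at the
preferred speed v0; the disordered state draws independent uniform
headings, while the ordered state gives every agent one common random
heading and then relaxes the spatial structure with a noiseless
equilibration run before time is relabelled to t = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import ModelParams, SwarmState
from .space import min_image_disp

__all__ = [
    "InitSpec",
    "default_min_dist",
    "place_min_dist",
    "random_unit_vectors",
    "init_disordered",
    "init_ordered",
]


def default_min_dist(N: int, L: float) -> float:
    """Minimum initial pair distance, 0.6 L N^(-1/3)."""
    return 0.6 * L * N ** (-1.0 / 3.0)


@dataclass(frozen=True)
class InitSpec:
    """How to build the starting state.

    ``equilibration`` only applies to the ordered mode; the production
    default of 1e5 s is cluster-scale, so desk-scale runs shorten it.
    """

    mode: str = "disordered"  # "disordered" | "ordered"
    min_dist: Optional[float] = None  # None -> 0.6 L N^(-1/3)
    equilibration: float = 1e5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("disordered", "ordered"):
            raise ValueError(f"unknown init mode {self.mode!r}")
        if self.min_dist is not None and self.min_dist <= 0:
            raise ValueError("min_dist must be > 0")
        if self.equilibration < 0:
            raise ValueError("equilibration must be >= 0")


def place_min_dist(
    N: int,
    L: float,
    min_dist: float,
    rng: np.random.Generator,
    max_attempts: int = 100_000,
) -> np.ndarray:
    """N positions uniform in the box, all minimum-image pair distances
    >= ``min_dist``, by sequential insertion with rejection.

    Raises when the attempt budget runs out, reporting the packing
    fraction (sphere volume at radius min_dist/2 over box volume) of the
    requested configuration.
    """
    if max_attempts < N:
        raise ValueError("max_attempts must be >= N")
    positions = np.empty((N, 3))
    placed = 0
    attempts = 0
    md2 = min_dist * min_dist
    while placed < N:
        if attempts >= max_attempts:
            packing = N * (4 / 3) * math.pi * (min_dist / 2) ** 3 / L**3
            raise RuntimeError(
                f"could not place {N} agents at min_dist={min_dist:g} in "
                f"L={L:g} after {max_attempts} attempts "
                f"(packing fraction {packing:.3f})"
            )
        cand = rng.uniform(0.0, L, size=3)
        attempts += 1
        ok = True
        for k in range(placed):
            d = min_image_disp(cand, positions[k], L)
            if float(d @ d) < md2:
                ok = False
                break
        if ok:
            positions[placed] = cand
            placed += 1
    return positions


def random_unit_vectors(n: int, rng: np.random.Generator) -> np.ndarray:
    """n i.i.d. directions uniform on the unit sphere (normalised Gaussians)."""
    g = rng.standard_normal((n, 3))
    norms = np.linalg.norm(g, axis=1, keepdims=True)
    bad = norms[:, 0] == 0.0
    while bad.any():  # pragma: no cover - probability zero
        g[bad] = rng.standard_normal((int(bad.sum()), 3))
        norms = np.linalg.norm(g, axis=1, keepdims=True)
        bad = norms[:, 0] == 0.0
    return g / norms


def init_disordered(
    params: ModelParams,
    rng: np.random.Generator,
    min_dist: Optional[float] = None,
) -> SwarmState:
    """Random positions (minimum-distance constrained) and N independent
    random headings, every speed exactly v0, at t = 0."""
    if min_dist is None:
        min_dist = default_min_dist(params.N, params.L)
    pos = place_min_dist(params.N, params.L, min_dist, rng)
    vel = params.v0 * random_unit_vectors(params.N, rng)
    return SwarmState(0.0, pos, vel)


def init_ordered(
    params: ModelParams,
    rng: np.random.Generator,
    equilibration: float = 1e5,
    min_dist: Optional[float] = None,
    record_every: Optional[float] = None,
) -> SwarmState:
    """Aligned velocities (one common random heading at speed v0), random
    constrained positions, then a noiseless, zero-delay equilibration run
    so the spatial structure relaxes; the returned state is relabelled
    t = 0.

    With ``equilibration = 0`` the state is perfectly aligned (E = 1).
    """
    if min_dist is None:
        min_dist = default_min_dist(params.N, params.L)
    pos = place_min_dist(params.N, params.L, min_dist, rng)
    heading = random_unit_vectors(1, rng)[0]
    vel = np.tile(params.v0 * heading, (params.N, 1))
    state = SwarmState(0.0, pos, vel)
    if equilibration > 0:
        from .integrator import run  # local import: integrator imports this module's siblings

        eq_params = params.with_(xi=0.0, t_d=0.0)
        if record_every is None:
            record_every = max(params.dt, equilibration / 100)
            record_every = round(record_every / params.dt) * params.dt
        result = run(state, eq_params, T=equilibration, record_every=record_every,
                     seed=0, use_history=False)
        state = result.final_state
        state.t = 0.0
    return state


def build_initial_state(params: ModelParams, spec: InitSpec) -> SwarmState:
    """Dispatch on :class:`InitSpec`."""
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "disordered":
        return init_disordered(params, rng, min_dist=spec.min_dist)
    return init_ordered(params, rng, equilibration=spec.equilibration,
                        min_dist=spec.min_dist)
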