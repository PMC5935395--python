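"""Reproducible drivers for the macroscopic experiments.

Three protocols are packaged here:

* **order_transition** — independent disordered starts, tracking how each
  run's efficiency jumps from the O(N^-1/2) random level to E ~ 1;
* **noise_hysteresis** — for each noise amplitude xi, runs from both a
  disordered start and an equilibrated ordered start; a hysteresis window
  is a xi range where the ordered start keeps order while the disordered
  start never finds it (the signature of a discontinuous transition);
* **delay_sweep** — runs over a grid of interaction delays t_d from both
  start modes, measuring the ordering rate (disordered starts) and the
  persistence of order (ordered starts).

Every output row carries the seed, a parameter hash and the code version,
and identical specs reproduce identical noiseless outputs (and identical
noisy outputs for the same seeds).  Scaled-down presets (N = 50 at the
production density, horizons of 10^3-10^4 s) accompany the production
presets, whose 500-run, 10^6 s ensembles are cluster-scale; the driver
counts the planned force evaluations up front and warns when a spec goes
beyond a desk-scale budget.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .initial import default_min_dist, init_disordered, init_ordered
from .integrator import RunResult, run
from .model import ModelParams
from .observables import (
    EfficiencySeries,
    EnsembleSummary,
    ensemble_histogram,
    transition_time,
)

__all__ = [
    "ExperimentSpec",
    "order_transition",
    "noise_hysteresis",
    "delay_sweep",
    "desk_scale_params",
    "paper_scale_params",
    "PAPER_DENSITY",
]

logger = logging.getLogger(__name__)

#: Agent number density N / L^3 of the production setup (200 agents in a
#: 50 m box).
PAPER_DENSITY = 200 / 50**3

#: Force-evaluation budget above which a spec is flagged as beyond desk scale.
DESK_STEP_BUDGET = 5e8

#: Tail-E classification thresholds: ordered above, disordered below,
#: undecided in between.
ORDERED_E = 0.8
DISORDERED_E = 0.3


def paper_scale_params(**overrides) -> ModelParams:
    """Production parameters: N = 200 in an L = 50 m box."""
    base = dict(N=200, L=50.0, v0=5.0, tau=1.0, mass=1.0, c=1.0, R=10.0,
                xi=0.0, dt=1e-3, t_d=0.0)
    base.update(overrides)
    return ModelParams(**base)


def desk_scale_params(N: int = 50, **overrides) -> ModelParams:
    """Scaled-down parameters: fewer agents at the production density.

    The box side follows from holding N / L^3 fixed; all other constants
    are the production values.
    """
    L = (N / PAPER_DENSITY) ** (1 / 3)
    base = dict(N=N, L=L, v0=5.0, tau=1.0, mass=1.0, c=1.0, R=10.0,
                xi=0.0, dt=1e-3, t_d=0.0)
    base.update(overrides)
    return ModelParams(**base)


@dataclass(frozen=True)
class ExperimentSpec:
    """A fully seeded, reproducible experiment description."""

    kind: str  # order_transition | noise_hysteresis | delay_sweep
    params: ModelParams = field(default_factory=lambda: desk_scale_params())
    n_runs: int = 5
    horizon: float = 1e4
    record_every: float = 10.0
    seeds: Optional[Tuple[int, ...]] = None  # None -> 1..n_runs
    equilibration: float = 1e3  # ordered-start relaxation time (s)
    xi_grid: Tuple[float, ...] = (0.0, 10.0, 20.0, 50.0, 100.0)
    delay_grid_ms: Tuple[float, ...] = (0.0, 10.0, 20.0, 50.0)
    tail_fraction: float = 0.1
    out_dir: Optional[Path] = None

    def __post_init__(self) -> None:
        if self.kind not in ("order_transition", "noise_hysteresis", "delay_sweep"):
            raise ValueError(f"unknown experiment kind {self.kind!r}")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")
        seeds = self.run_seeds
        if len(set(seeds)) != len(seeds):
            raise ValueError("seeds must be distinct")
        k = round(self.horizon / self.params.dt)
        if abs(self.horizon - k * self.params.dt) > 1e-6 * self.params.dt:
            raise ValueError("horizon must be a multiple of dt")

    @property
    def run_seeds(self) -> Tuple[int, ...]:
        return self.seeds if self.seeds is not None else tuple(range(1, self.n_runs + 1))

    def param_hash(self) -> str:
        payload = json.dumps(asdict(self.params), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def planned_steps(self, multiplicity: int = 1) -> float:
        return self.horizon / self.params.dt * self.n_runs * multiplicity

    def guard(self, multiplicity: int = 1) -> None:
        steps = self.planned_steps(multiplicity)
        if steps > DESK_STEP_BUDGET:
            logger.warning(
                "spec plans %.2g integration steps, above the desk-scale "
                "budget of %.2g; consider the scaled-down presets or a "
                "cluster", steps, DESK_STEP_BUDGET,
            )


def _provenance(spec: ExperimentSpec, seed: int) -> dict:
    from . import __version__

    return {"seed": seed, "param_hash": spec.param_hash(),
            "code_version": __version__}


def _start_state(spec: ExperimentSpec, params: ModelParams, mode: str, seed: int):
    rng = np.random.default_rng(seed)
    if mode == "disordered":
        return init_disordered(params, rng)
    return init_ordered(params, rng, equilibration=spec.equilibration)


def classify(tail_e: float) -> str:
    if tail_e > ORDERED_E:
        return "ordered"
    if tail_e < DISORDERED_E:
        return "disordered"
    return "undecided"


@dataclass
class OrderTransitionResult:
    runs: List[RunResult]
    summary: EnsembleSummary
    table: pd.DataFrame  # per-run: seed, E_final, tail E, transition time, class

    @property
    def mean_curve(self) -> EfficiencySeries:
        vals = np.stack([r.efficiency for r in self.runs]).mean(axis=0)
        return EfficiencySeries(self.runs[0].times, vals)


def order_transition(spec: ExperimentSpec) -> OrderTransitionResult:
    """Disordered-start ensemble: per-run series, histogram, Binder,
    transition times."""
    spec.guard()
    params = spec.params
    results: List[RunResult] = []
    rows = []
    for seed in spec.run_seeds:
        logger.info("order_transition: seed %d start (horizon %.3g s)",
                    seed, spec.horizon)
        t_wall = time.perf_counter()
        try:
            state = _start_state(spec, params, "disordered", seed)
            res = run(state, params, T=spec.horizon,
                      record_every=spec.record_every, seed=seed)
        except FloatingPointError as exc:  # pragma: no cover - defensive
            logger.error("run with seed %d failed: %s", seed, exc)
            continue
        elapsed = time.perf_counter() - t_wall
        logger.info("order_transition: seed %d done, %.3g steps/s",
                    seed, spec.horizon / params.dt / max(elapsed, 1e-9))
        results.append(res)
        tail = res.series.tail_mean(spec.tail_fraction)
        rows.append(
            {
                **_provenance(spec, seed),
                "E_initial": res.efficiency[0],
                "E_final": res.efficiency[-1],
                "tail_E": tail,
                "transition_time": transition_time(res.series, ORDERED_E),
                "state": classify(tail),
            }
        )
    if not results:
        raise RuntimeError("all runs failed")
    summary = ensemble_histogram(
        [r.series for r in results], binder_N=None
    )
    table = pd.DataFrame(rows)
    out = OrderTransitionResult(runs=results, summary=summary, table=table)
    if spec.out_dir is not None:
        _write_order_outputs(spec, out)
    return out


def _write_order_outputs(spec: ExperimentSpec, out: OrderTransitionResult) -> None:
    from .io import write_metadata, write_series_csv

    d = Path(spec.out_dir)
    d.mkdir(parents=True, exist_ok=True)
    for res in out.runs:
        write_series_csv(d / f"efficiency_seed{res.seed}.csv", res.series)
    out.table.to_csv(d / "runs.csv", index=False)
    out.summary.to_frame().to_csv(d / "ensemble_histogram.csv", index=False)
    write_metadata(d / "metadata.json", spec.params, seed=-1,
                   kind=spec.kind, seeds=list(spec.run_seeds),
                   horizon=spec.horizon, record_every=spec.record_every)


def noise_hysteresis(spec: ExperimentSpec) -> pd.DataFrame:
    """Tail efficiency per (xi, start mode); flags the hysteresis window.

    Returns a tidy table with one row per (xi, mode, seed) plus the
    aggregate mean per (xi, mode); a window row is marked where the
    ordered start keeps order while the disordered start stays disordered.
    """
    if len(spec.xi_grid) == 0:
        raise ValueError("xi_grid must be nonempty")
    spec.guard(multiplicity=2 * len(spec.xi_grid))
    rows = []
    for xi in spec.xi_grid:
        params = spec.params.with_(xi=float(xi))
        for mode in ("disordered", "ordered"):
            for seed in spec.run_seeds:
                logger.info("noise_hysteresis: xi=%g %s seed %d",
                            xi, mode, seed)
                state = _start_state(spec, params, mode, seed)
                res = run(state, params, T=spec.horizon,
                          record_every=spec.record_every, seed=seed)
                tail = res.series.tail_mean(spec.tail_fraction)
                rows.append(
                    {
                        **_provenance(spec, seed),
                        "xi": float(xi),
                        "start": mode,
                        "tail_E": tail,
                        "state": classify(tail),
                    }
                )
    df = pd.DataFrame(rows)
    means = (
        df.pivot_table(index="xi", columns="start", values="tail_E")
        .rename(columns=lambda s: f"mean_tail_E_{s}")
        .reset_index()
    )
    means["hysteresis"] = (
        (means["mean_tail_E_ordered"] > ORDERED_E)
        & (means["mean_tail_E_disordered"] < DISORDERED_E)
    )
    df = df.merge(means, on="xi")
    if spec.out_dir is not None:
        d = Path(spec.out_dir)
        d.mkdir(parents=True, exist_ok=True)
        df.to_csv(d / "noise_hysteresis.csv", index=False)
    return df


def delay_sweep(spec: ExperimentSpec) -> pd.DataFrame:
    """Ordering rate and order persistence across interaction delays.

    For each delay on the grid (milliseconds) runs start from both modes;
    disordered starts report the transition time (the ordering rate),
    ordered starts the tail efficiency (persistence).
    """
    for td_ms in spec.delay_grid_ms:
        td = td_ms * 1e-3
        k = round(td / spec.params.dt)
        if abs(td - k * spec.params.dt) > 1e-9 * max(spec.params.dt, td):
            raise ValueError(f"delay {td_ms} ms is not a multiple of dt")
    spec.guard(multiplicity=2 * len(spec.delay_grid_ms))
    rows = []
    for td_ms in spec.delay_grid_ms:
        params = spec.params.with_(t_d=td_ms * 1e-3)
        for mode in ("disordered", "ordered"):
            for seed in spec.run_seeds:
                logger.info("delay_sweep: t_d=%g ms %s seed %d",
                            td_ms, mode, seed)
                state = _start_state(spec, params, mode, seed)
                res = run(state, params, T=spec.horizon,
                          record_every=spec.record_every, seed=seed)
                tail = res.series.tail_mean(spec.tail_fraction)
                tt = transition_time(res.series, ORDERED_E)
                rows.append(
                    {
                        **_provenance(spec, seed),
                        "t_d_ms": float(td_ms),
                        "start": mode,
                        "tail_E": tail,
                        "transition_time": tt,
                        "state": classify(tail),
                    }
                )
    df = pd.DataFrame(rows)
    if spec.out_dir is not None:
        d = Path(spec.out_dir)
        d.mkdir(parents=True, exist_ok=True)
        df.to_csv(d / "delay_sweep.csv", index=False)
    return df
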