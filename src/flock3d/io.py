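"""Plain-text input/output: XYZ trajectories, CSV series, JSON metadata.

Trajectory frames use extended-XYZ conventions — atom count, a comment
line carrying the simulation time and efficiency, then one
``A x y z vx vy vz`` line per agent — so standard molecular viewers can
load them.  Observable series and flat trajectories are CSV.  Each run
can carry a JSON sidecar with the parameters, seed and code version for
provenance.
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path
from typing import Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .model import ModelParams, SwarmState
from .observables import EfficiencySeries

__all__ = [
    "write_xyz_frame",
    "read_xyz",
    "write_series_csv",
    "read_series_csv",
    "write_trajectory_csv",
    "write_metadata",
    "read_metadata",
]


def write_xyz_frame(fh, state: SwarmState, efficiency: Optional[float] = None) -> None:
    """Append one frame to an open text handle."""
    fh.write(f"{state.N}\n")
    comment = f"t={state.t:.17g}"
    if efficiency is not None:
        comment += f" E={efficiency:.17g}"
    fh.write(comment + "\n")
    for r, v in zip(state.positions, state.velocities):
        fh.write(
            f"A {r[0]:.17g} {r[1]:.17g} {r[2]:.17g} "
            f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n"
        )


def read_xyz(path) -> List[SwarmState]:
    """Read a multi-frame XYZ trajectory written by :func:`write_xyz_frame`."""
    frames: List[SwarmState] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        m = re.search(r"t=([-\d.eE+]+)", lines[i + 1])
        t = float(m.group(1)) if m else 0.0
        pos = np.empty((n, 3))
        vel = np.empty((n, 3))
        for k in range(n):
            parts = lines[i + 2 + k].split()
            pos[k] = [float(x) for x in parts[1:4]]
            vel[k] = [float(x) for x in parts[4:7]]
        frames.append(SwarmState(t, pos, vel))
        i += 2 + n
    return frames


def write_series_csv(path, series: EfficiencySeries) -> None:
    pd.DataFrame({"t": series.times, "E": series.values}).to_csv(path, index=False)


def read_series_csv(path) -> EfficiencySeries:
    df = pd.read_csv(path)
    return EfficiencySeries(df["t"].to_numpy(), df["E"].to_numpy())


def write_trajectory_csv(path, frames: Iterable[SwarmState]) -> None:
    """Flat long-form trajectory: t, agent, x, y, z, vx, vy, vz."""
    rows = []
    for st in frames:
        for i in range(st.N):
            rows.append(
                (st.t, i, *st.positions[i], *st.velocities[i])
            )
    pd.DataFrame(
        rows, columns=["t", "agent", "x", "y", "z", "vx", "vy", "vz"]
    ).to_csv(path, index=False)


def write_metadata(path, params: ModelParams, seed: int, **extra) -> None:
    from . import __version__

    meta = {
        "params": dataclasses.asdict(params),
        "seed": seed,
        "code_version": __version__,
    }
    meta.update(extra)
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_metadata(path) -> dict:
    return json.loads(Path(path).read_text())
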