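"""Order parameters and transition diagnostics.

The central quantity is the *efficiency*

    E(t) = |sum_i v_i(t)| / (N v0),

the normalised magnitude of the summed velocity vectors: 1 for perfect
alignment at the preferred speed, of order N^(-1/2) for random headings.
E may exceed 1 when many agents move faster than v0 and is deliberately
not clamped.

Ensembles of runs are summarised by a 2-D histogram over (log-spaced time,
E bins) and by the Binder cumulant

    B(E) = 1 - <E^4> / (3 <E^2>^2),

a fourth-moment ratio whose size dependence diagnoses whether the
order-disorder transition is bimodal (discontinuous) or continuous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import ModelParams, SwarmState

__all__ = [
    "EfficiencySeries",
    "EnsembleSummary",
    "efficiency",
    "binder_cumulant",
    "transition_time",
    "ensemble_histogram",
]


@dataclass
class EfficiencySeries:
    """Efficiency sampled on a strictly increasing time grid."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if len(self.times) > 1 and not (np.diff(self.times) > 0).all():
            raise ValueError("times must be strictly increasing")
        if (self.values < 0).any():
            raise ValueError("efficiency values must be >= 0")

    def __len__(self) -> int:
        return len(self.times)

    def tail_mean(self, fraction: float = 0.1) -> float:
        """Mean efficiency over the final ``fraction`` of the time span."""
        t0 = self.times[-1] - fraction * (self.times[-1] - self.times[0])
        sel = self.times >= t0
        return float(self.values[sel].mean())


def efficiency(state: SwarmState, params: ModelParams) -> float:
    """E = |sum v_i| / (N v0); not clamped above 1."""
    total = state.velocities.sum(axis=0)
    return float(np.linalg.norm(total) / (state.N * params.v0))


def binder_cumulant(samples: Sequence[float], N: Optional[int] = None) -> float:
    """Binder cumulant 1 - <E^4>/(3 <E^2>^2) with plain moment estimators.

    ``N`` requests the size-normalised variant B/N.  All-zero samples make
    the ratio undefined and raise.
    """
    e = np.asarray(samples, dtype=np.float64)
    if e.size == 0:
        raise ValueError("need at least one sample")
    m2 = float(np.mean(e**2))
    if m2 == 0.0:
        raise ZeroDivisionError("Binder cumulant undefined for all-zero samples")
    m4 = float(np.mean(e**4))
    b = 1.0 - m4 / (3.0 * m2 * m2)
    if N is not None:
        b /= N
    return b


def transition_time(
    series: EfficiencySeries, threshold: float, dwell: Optional[float] = None
) -> Optional[float]:
    """Earliest recorded time after which E stays above ``threshold`` for
    at least the ``dwell`` window.

    Operates on the recorded cadence without interpolation; ``dwell``
    defaults to one recording interval.  Returns ``None`` if the series
    never sustains the threshold.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    t, v = series.times, series.values
    if dwell is None:
        dwell = float(t[1] - t[0]) if len(t) > 1 else 0.0
    if dwell < 0:
        raise ValueError("dwell must be >= 0")
    above = v > threshold
    for i in np.flatnonzero(above):
        j = np.searchsorted(t, t[i] + dwell, side="left")
        if j > len(t) - 1:
            if above[i:].all() and t[-1] - t[i] >= dwell:
                return float(t[i])
            return None
        if above[i : j + 1].all():
            return float(t[i])
    return None


@dataclass
class EnsembleSummary:
    """2-D run-count histogram over (time bin, efficiency bin) plus the
    per-time Binder cumulant of the ensemble."""

    time_bins: np.ndarray  # representative times, ratio-spaced
    e_bin_edges: np.ndarray
    counts: np.ndarray  # (n_time_bins, n_e_bins) run counts
    binder: np.ndarray  # Binder cumulant per time bin
    run_count: int

    def to_frame(self):
        """Long-form (time_bin, e_bin, count) table for CSV export."""
        import pandas as pd

        tt, ee = np.meshgrid(
            np.arange(len(self.time_bins)), np.arange(self.counts.shape[1]),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "time": self.time_bins[tt.ravel()],
                "e_bin_low": self.e_bin_edges[ee.ravel()],
                "count": self.counts.ravel().astype(int),
            }
        )


def ensemble_histogram(
    runs: Sequence[EfficiencySeries],
    time_ratio: float = 10 ** (1 / 30),
    e_bin_width: float = 0.01,
    binder_N: Optional[int] = None,
) -> EnsembleSummary:
    """Distribution of an ensemble of efficiency series over time.

    Times are subsampled onto a ratio-spaced grid (adjacent sampled times
    differ by a factor ``time_ratio``); at each sampled time the runs'
    efficiencies are binned with width ``e_bin_width`` and the Binder
    cumulant across runs is computed.  All runs must share the recording
    cadence.
    """
    if len(runs) == 0:
        raise ValueError("need at least one run")
    t0 = runs[0].times
    for r in runs[1:]:
        if len(r) != len(t0) or not np.allclose(r.times, t0):
            raise ValueError("all runs must share the recording cadence")

    # ratio-spaced subsample of the recorded (positive) times
    pos = t0[t0 > 0]
    if pos.size == 0:
        raise ValueError("need at least one positive recording time")
    sel_idx = []
    target = pos[0]
    for i, t in enumerate(t0):
        if t > 0 and t >= target:
            sel_idx.append(i)
            while target <= t:
                target *= time_ratio
    sel_idx = np.asarray(sel_idx, dtype=int)

    vals = np.stack([r.values for r in runs])  # (n_runs, n_times)
    vmax = float(vals.max())
    n_e_bins = max(1, int(np.ceil((vmax + 1e-12) / e_bin_width)))
    edges = np.arange(n_e_bins + 1) * e_bin_width
    counts = np.empty((len(sel_idx), n_e_bins), dtype=np.int64)
    binder = np.empty(len(sel_idx))
    for out_i, i in enumerate(sel_idx):
        counts[out_i], _ = np.histogram(vals[:, i], bins=edges)
        binder[out_i] = binder_cumulant(vals[:, i], N=binder_N)
    return EnsembleSummary(
        time_bins=t0[sel_idx],
        e_bin_edges=edges,
        counts=counts,
        binder=binder,
        run_count=len(runs),
    )
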