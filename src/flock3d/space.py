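"""Periodic-box geometry and cell-grid neighbour enumeration.

Distances are always measured with the minimum-image convention: the pair
displacement is taken to the nearest periodic image, each component shifted
into ``[-L/2, L/2)``.  Interaction pairs are found with a 3-D cell grid of
``floor(L/R)`` cells per side (cell side ``L / floor(L/R) >= R``), scanning
an agent's own cell and the 26 neighbouring cells; for any cell side at
least as large as the cutoff this search is exhaustive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import ModelParams, SwarmState

__all__ = ["wrap_position", "min_image_disp", "CellGrid", "neighbor_pairs"]


def wrap_position(pos: np.ndarray, L: float) -> np.ndarray:
    """Map each coordinate into ``[0, L)`` by modular arithmetic (idempotent)."""
    pos = np.asarray(pos, dtype=np.float64)
    out = pos - L * np.floor(pos / L)
    # guard against pos = -eps mapping to exactly L through round-off
    out[out >= L] -= L
    return out


def min_image_disp(ri: np.ndarray, rj: np.ndarray, L: float) -> np.ndarray:
    """Minimum-image displacement ``ri - rj``, components in ``[-L/2, L/2)``."""
    d = np.asarray(ri, dtype=np.float64) - np.asarray(rj, dtype=np.float64)
    return d - L * np.floor(d / L + 0.5)


@dataclass
class CellGrid:
    """Assignment of agents to the cells of the 3-D search grid.

    ``cells_per_side = floor(L/R)`` (at least 3 by the model invariant) and
    ``cell_side = L / cells_per_side`` so the grid tiles the box exactly.
    """

    cells_per_side: int
    cell_side: float
    assignment: dict  # (cx, cy, cz) -> list of agent indices

    @classmethod
    def build(cls, positions: np.ndarray, L: float, R: float) -> "CellGrid":
        m = math.floor(L / R)
        if m < 3:
            raise ValueError(
                f"cell grid needs floor(L/R) >= 3 for an exhaustive 27-cell "
                f"search; got L={L}, R={R}"
            )
        side = L / m
        cells = np.floor(positions / side).astype(np.int64)
        np.clip(cells, 0, m - 1, out=cells)  # round-off guard at the top face
        assignment: dict = {}
        for idx, key in enumerate(map(tuple, cells)):
            assignment.setdefault(key, []).append(idx)
        return cls(cells_per_side=m, cell_side=side, assignment=assignment)


def neighbor_pairs(state: SwarmState, params: ModelParams):
    """All unordered pairs at minimum-image distance strictly below R.

    Returns a list of ``(i, j, disp, dist)`` with ``i < j``, each pair
    reported once; ``disp`` is the minimum-image displacement
    ``r_i - r_j``.  The cutoff is open ("below" the radius), so a pair at
    exactly ``dist == R`` is excluded.
    """
    L, R = params.L, params.R
    pos = state.positions
    grid = CellGrid.build(pos, L, R)
    m = grid.cells_per_side
    pairs = []
    seen_cell_pairs = set()
    for (cx, cy, cz), members in grid.assignment.items():
        for ox in (-1, 0, 1):
            for oy in (-1, 0, 1):
                for oz in (-1, 0, 1):
                    key2 = ((cx + ox) % m, (cy + oy) % m, (cz + oz) % m)
                    if key2 not in grid.assignment:
                        continue
                    a, b = (cx, cy, cz), key2
                    pair_key = (a, b) if a <= b else (b, a)
                    if pair_key in seen_cell_pairs:
                        continue
                    seen_cell_pairs.add(pair_key)
                    others = grid.assignment[key2]
                    if a == b:
                        for ii in range(len(members)):
                            for jj in range(ii + 1, len(members)):
                                _maybe_add(pairs, pos, members[ii], members[jj], L, R)
                    else:
                        for i in members:
                            for j in others:
                                _maybe_add(pairs, pos, i, j, L, R)
    pairs.sort(key=lambda rec: (rec[0], rec[1]))
    return pairs


def _maybe_add(pairs, pos, i, j, L, R):
    if i > j:
        i, j = j, i
    d = min_image_disp(pos[i], pos[j], L)
    dist = float(np.linalg.norm(d))
    if dist < R:
        pairs.append((i, j, d, dist))


def brute_force_pairs(state: SwarmState, params: ModelParams):
    """O(N^2) all-pairs scan; the reference oracle for :func:`neighbor_pairs`."""
    L, R = params.L, params.R
    pos = state.positions
    out = []
    for i in range(state.N):
        for j in range(i + 1, state.N):
            d = min_image_disp(pos[i], pos[j], L)
            dist = float(np.linalg.norm(d))
            if dist < R:
                out.append((i, j, d, dist))
    return out
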