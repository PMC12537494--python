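"""Spatial block cross-validation.

Plots are binned into axis-aligned 6-arcmin (0.1 degree) longitude/latitude
cells; whole cells are then assigned to folds so that fold sizes are
balanced by plot count, not by block count.  Keeping every block intact
prevents near-duplicate plots (spatially adjacent, near-identical species
lists) from straddling the train/test boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .plot_data import PlotHeader

__all__ = ["BlockId", "FoldAssignment", "block_id", "assign_folds",
           "assign_plot_folds"]


@dataclass(frozen=True, order=True)
class BlockId:
    """Integer grid cell indices (east, north) at a stated cell size."""

    east: int
    north: int


def _grid_index(coord: float, cell_deg: float) -> int:
    """floor(coord / cell) with a half-ulp guard.

    0.1 is not representable in binary floating point, so exact multiples
    of the cell size (e.g. 5.2 / 0.1 = 51.999...) would otherwise land in
    the wrong cell; values within 1e-9 of an integer snap to it.
    """
    x = coord / cell_deg
    nearest = round(x)
    if abs(x - nearest) < 1e-9:
        return int(nearest)
    return math.floor(x)


def block_id(lon: float, lat: float, cell_deg: float = 0.1) -> BlockId:
    """Grid cell of a coordinate pair (default 6-arcmin cells)."""
    if not -180.0 <= lon <= 180.0 or not -90.0 <= lat <= 90.0:
        raise ValueError(f"coordinate out of range: ({lon}, {lat})")
    return BlockId(_grid_index(lon, cell_deg), _grid_index(lat, cell_deg))


@dataclass
class FoldAssignment:
    k: int
    plot_to_fold: dict[str, int]
    block_to_fold: dict[BlockId, int]

    def fold_sizes(self) -> list[int]:
        sizes = [0] * self.k
        for f in self.plot_to_fold.values():
            sizes[f] += 1
        return sizes


def assign_folds(block_counts: Mapping[BlockId, int], k: int = 10,
                 seed: int = 0) -> dict[BlockId, int]:
    """Assign whole blocks to k folds, balancing fold plot counts.

    Greedy longest-processing-time: blocks sorted by descending count
    (ties by block id), each placed on the currently lightest fold (ties by
    lowest fold index).  Deterministic; ``seed`` is accepted for interface
    stability but the assignment has no random component.
    """
    if k > len(block_counts):
        raise ValueError(f"k={k} exceeds number of blocks ({len(block_counts)})")
    order = sorted(block_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    loads = [0] * k
    assignment: dict[BlockId, int] = {}
    for block, count in order:
        fold = min(range(k), key=lambda f: (loads[f], f))
        assignment[block] = fold
        loads[fold] += count
    return assignment


def assign_plot_folds(headers: Sequence[PlotHeader], k: int = 10,
                      cell_deg: float = 0.1, seed: int = 0) -> FoldAssignment:
    """Block plots spatially and assign plot-count-balanced folds."""
    plot_block = {h.plot_id: block_id(h.longitude, h.latitude, cell_deg)
                  for h in headers}
    counts: dict[BlockId, int] = {}
    for b in plot_block.values():
        counts[b] = counts.get(b, 0) + 1
    block_fold = assign_folds(counts, k=k, seed=seed)
    plot_fold = {pid: block_fold[b] for pid, b in plot_block.items()}
    return FoldAssignment(k, plot_fold, block_fold)
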