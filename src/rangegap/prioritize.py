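"""Greedy conservation prioritization by iterative cell removal.

A defined, reproducible stand-in for Zonation-style ranking under the
core-area (minimum marginal loss) rule: at every step the cell whose removal
costs the least to the worst-affected species is deleted, so cells that are
a large fraction of *some* species' remaining range survive longest. The
removal order defines a per-cell importance rank in (0, 1]; rarity-restricted
species therefore keep their strongholds near the top of the ranking, which
is the complementarity/irreplaceability behavior the rule is chosen for.

No acceleration ("warp") is applied: cells are removed one at a time, which
is affordable at the grid sizes this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import RasterGrid


@dataclass
class ImportanceRaster:
    """Per-cell importance rank from greedy removal.

    ``rank_fraction`` maps the N valid cells bijectively onto
    {1/N, 2/N, ..., 1}; cells removed later rank higher. ``removal_order``
    lists flat (row-major) cell indices in the order they were removed.
    """

    grid: RasterGrid
    rank_fraction: np.ndarray   # (n_rows, n_cols), NaN at nodata
    removal_order: np.ndarray   # (n_valid,) flat indices


def rank_cells(ranges: np.ndarray, grid: RasterGrid,
               weights: np.ndarray | None = None) -> ImportanceRaster:
    """Rank valid cells by greedy core-area cell removal.

    Parameters
    ----------
    ranges : ndarray, shape (n_species, n_rows, n_cols)
        Per-species presence (0/1) or suitability values; NaN treated as 0.
    grid : RasterGrid
        Analysis lattice; only valid cells are ranked.
    weights : ndarray, optional
        Positive per-species weights (default all 1).

    At each step the removed cell is the one minimizing
    ``delta(cell) = max_s weight_s * value_s(cell) / remaining_total_s``,
    i.e. the cell least critical to its most-dependent species; ties break
    toward the lower flat cell index. Removal position p (1-based) over N
    valid cells gives rank_fraction p/N.
    """
    vals3 = np.asarray(ranges, dtype=float)
    if vals3.ndim == 2:
        vals3 = vals3[None]
    n_species = vals3.shape[0]
    if n_species < 1:
        raise ValueError("at least one species is required")
    if vals3.shape[1:] != grid.shape:
        raise ValueError("range stack shape does not match the grid")
    w = np.ones(n_species) if weights is None else np.asarray(weights, dtype=float)
    if len(w) != n_species or np.any(w <= 0):
        raise ValueError("weights must be positive, one per species")

    flat_valid = np.nonzero(grid.mask.ravel())[0]
    n = len(flat_valid)
    vals = np.nan_to_num(vals3.reshape(n_species, -1)[:, flat_valid], nan=0.0)
    if np.any(vals < 0):
        raise ValueError("range values must be non-negative")
    totals = vals.sum(axis=1)
    if np.any(totals <= 0):
        bad = int(np.argmax(totals <= 0))
        raise ValueError(f"species {bad} has zero total value over valid cells")

    alive = np.ones(n, dtype=bool)
    order = np.empty(n, dtype=int)
    for step in range(n):
        idx_alive = np.nonzero(alive)[0]
        # totals are recomputed from the alive set each step so a species'
        # sole remaining cell scores delta exactly 1 (no subtraction drift)
        remaining = vals[:, idx_alive].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(remaining[:, None] > 0,
                            w[:, None] * vals[:, idx_alive] / remaining[:, None],
                            0.0)
        delta = frac.max(axis=0)
        pick = idx_alive[int(np.argmin(delta))]  # argmin returns first min → lowest index
        order[step] = pick
        alive[pick] = False
    rank = np.full(grid.n_rows * grid.n_cols, np.nan)
    rank[flat_valid[order]] = (np.arange(n) + 1) / n
    return ImportanceRaster(grid=grid,
                            rank_fraction=rank.reshape(grid.shape),
                            removal_order=flat_valid[order])


def mean_importance(importance: ImportanceRaster, cells: np.ndarray) -> float:
    """Arithmetic mean rank_fraction over a cell set (boolean mask)."""
    mask = np.asarray(cells, dtype=bool)
    if mask.shape != importance.grid.shape:
        raise ValueError("cell mask shape does not match the grid")
    if not mask.any():
        raise ValueError("cell set is empty")
    vals = importance.rank_fraction[mask]
    if np.isnan(vals).any():
        raise ValueError("cell set includes nodata cells")
    return float(vals.mean())
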