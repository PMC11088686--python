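"""Jaccard-gated ensemble averaging and the basin spatial constraint.

The ensemble keeps only the learners whose Jaccard performance exceeds the
species' across-learner mean, averages their suitability surfaces cell-wise,
and binarizes the average at the mean of the included learners' thresholds.
The binary range is then pruned to the basins that are predicted occupied
and connected — through chains of adjacent predicted basins — to a basin
holding an actual occurrence record, curbing overprediction in hydrologically
disconnected regions.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .occurrences import OccurrenceSet
from .sdm import FittedModel
from .synth import BasinMap


@dataclass
class EnsembleResult:
    """Mean suitability of the Jaccard-gated learner subset, binarized."""

    included_learners: tuple[str, ...]
    suitability: np.ndarray   # (n_rows, n_cols) in [0, 1]
    threshold: float
    binary: np.ndarray        # bool presence/absence


@dataclass
class ConstrainedRange:
    """Binary range pruned to occurrence-connected predicted basins."""

    binary: np.ndarray
    retained_basins: frozenset


def ensemble(models: list[FittedModel]) -> EnsembleResult:
    """Average the suitability of models beating the mean Jaccard performance.

    A model is included iff its Jaccard value is strictly greater than the
    mean Jaccard across the species' models; when no model is strictly above
    the mean (all tied) every model is included. The ensemble threshold is
    the mean of the included models' thresholds.
    """
    if not models:
        raise ValueError("ensemble requires at least one fitted model")
    j = np.array([m.metrics["jaccard"] for m in models], dtype=float)
    if np.isnan(j).any():
        raise ValueError("all models must have a defined Jaccard value")
    mean_j = j.mean()
    included = [m for m, jv in zip(models, j) if jv > mean_j]
    if not included:
        included = list(models)
    suit = np.mean([m.suitability for m in included], axis=0)
    thr = float(np.mean([m.threshold for m in included]))
    valid = np.isfinite(suit)
    binary = np.zeros(suit.shape, dtype=bool)
    binary[valid] = suit[valid] >= thr
    return EnsembleResult(
        included_learners=tuple(m.learner_id for m in included),
        suitability=suit, threshold=thr, binary=binary,
    )


def spatial_constraint(binary: np.ndarray, basins: BasinMap,
                       occ: OccurrenceSet) -> ConstrainedRange:
    """Retain predicted basins reachable from occurrence-holding basins.

    A basin is *predicted* if at least one presence cell falls in it. Seed
    basins are predicted basins containing at least one occurrence record;
    the retained set is the seeds plus every predicted basin reachable from
    a seed through chains of edge-adjacent predicted basins. Presence cells
    outside retained basins are zeroed.
    """
    if len(occ) == 0:
        raise ValueError("occurrence set is empty")
    labels = basins.labels
    binary = np.asarray(binary, dtype=bool)
    if binary.shape != labels.shape:
        raise ValueError("binary raster and basin map shapes differ")
    predicted = set(np.unique(labels[binary & (labels >= 0)]).tolist())
    rc = basins.grid.points_to_cells(occ.points)
    occ_basins = set()
    for r, c in rc:
        if r < 0 or labels[r, c] < 0:
            raise ValueError("an occurrence record falls outside every basin")
        occ_basins.add(int(labels[r, c]))
    seeds = predicted & occ_basins
    retained = set(seeds)
    queue = deque(seeds)
    while queue:
        b = queue.popleft()
        for nb in basins.neighbors(b):
            if nb in predicted and nb not in retained:
                retained.add(nb)
                queue.append(nb)
    keep = np.isin(labels, sorted(retained)) if retained else np.zeros_like(binary)
    return ConstrainedRange(binary=binary & keep, retained_basins=frozenset(retained))
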