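"""Dimension reduction of the environmental stack.

Correlated predictor layers are replaced by the leading principal-component
score surfaces, retaining the minimal set of axes whose cumulative explained
variance reaches a target (default 95%). Because input layers are
standardized, PCA on the covariance of valid cells is equivalent to
correlation-matrix PCA, which is what multicollinearity reduction calls for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .grid import RasterGrid, raster_values_at
from .synth import EnvStack


@dataclass
class PcaStack:
    """Principal-component score rasters plus loadings and explained fractions.

    ``scores`` holds only the retained axes; ``loadings`` is the full
    layers × axes matrix and ``explained`` the full per-axis variance
    fractions (non-increasing), so reconstruction diagnostics remain
    available.
    """

    grid: RasterGrid
    scores: np.ndarray        # (n_retained, n_rows, n_cols), NaN at nodata
    loadings: np.ndarray      # (n_layers, n_axes) — full decomposition
    explained: np.ndarray     # (n_axes,) variance fractions, non-increasing
    n_retained: int
    mean: np.ndarray          # per-layer mean over valid cells

    @property
    def n_axes(self) -> int:
        return self.scores.shape[0]

    def values_at(self, points: np.ndarray) -> np.ndarray:
        """(n_points, n_retained) score matrix at point locations."""
        return np.column_stack(
            [raster_values_at(self.scores[k], self.grid, points)
             for k in range(self.n_retained)]
        )

    def valid_matrix(self) -> np.ndarray:
        """(n_valid_cells, n_retained) score matrix over valid cells."""
        m = self.grid.mask
        return np.column_stack([self.scores[k][m] for k in range(self.n_retained)])

    def reconstruction_error(self, stack: EnvStack) -> float:
        """Squared-Frobenius relative error of reconstructing the stack
        from the retained axes; bounded by the discarded variance fraction."""
        x = stack.valid_matrix() - self.mean
        s = self.valid_matrix()
        x_hat = s @ self.loadings[:, : self.n_retained].T
        return float(np.sum((x - x_hat) ** 2) / np.sum(x ** 2))


def pca_reduce(stack: EnvStack, variance_target: float = 0.95) -> PcaStack:
    """Eigendecompose the stack's cell-wise covariance and retain leading axes.

    Retains the minimal set of leading components whose cumulative explained
    variance is at least ``variance_target``. The sign of each axis is fixed
    so its largest-magnitude loading is positive, making outputs
    deterministic.
    """
    if stack.n_layers < 2:
        raise ValueError("PCA needs at least 2 layers")
    if not 0 < variance_target <= 1:
        raise ValueError("variance_target must lie in (0, 1]")
    x = stack.valid_matrix()
    if len(x) < stack.n_layers:
        raise ValueError(
            f"only {len(x)} valid cells for {stack.n_layers} layers; "
            "covariance would be rank-deficient"
        )
    pca = PCA(n_components=stack.n_layers, svd_solver="full")
    scores_flat = pca.fit_transform(x)
    loadings = pca.components_.T.copy()          # layers × axes
    explained = pca.explained_variance_ratio_.copy()
    # deterministic sign: largest-|loading| entry of each axis made positive
    for a in range(loadings.shape[1]):
        lead = np.argmax(np.abs(loadings[:, a]))
        if loadings[lead, a] < 0:
            loadings[:, a] *= -1
            scores_flat[:, a] *= -1
    cum = np.cumsum(explained)
    n_retained = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    n_retained = min(n_retained, stack.n_layers)
    grid = stack.grid
    scores = np.full((n_retained, grid.n_rows, grid.n_cols), np.nan)
    for a in range(n_retained):
        layer = np.full(grid.shape, np.nan)
        layer[grid.mask] = scores_flat[:, a]
        scores[a] = layer
    return PcaStack(grid=grid, scores=scores, loadings=loadings,
                    explained=explained, n_retained=n_retained,
                    mean=pca.mean_.copy())


def first_axis_values(stack: EnvStack, points: np.ndarray) -> np.ndarray:
    """First principal-component score at point locations.

    Convenience for occurrence thinning, which measures environmental
    autocorrelation along the stack's dominant gradient.
    """
    pcs = pca_reduce(stack, variance_target=1e-9)  # retains exactly one axis
    return pcs.values_at(points)[:, 0]
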