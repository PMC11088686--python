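"""Synthetic landscapes with known ground truth.

Everything downstream of raw data — occurrence cleaning, predictor reduction,
suitability modeling, prioritization and the protection gap analysis — can be
exercised on landscapes generated here: spatially autocorrelated environmental
layers, species with known Gaussian niches, occurrence samples biased toward
truly suitable cells, block-clustered protection categories and a contiguous
basin partition with a known adjacency graph.

The grid is abstract and planar: all cells are treated as equal-area, so the
latitude-dependent distortion of a real geographic lattice is deliberately
ignored.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import RasterGrid

#: protection category codes used throughout the package
CATEGORY_CODES = {"unprotected": 0, "SPA": 1, "SUA": 2, "IT": 3}
CODE_LABELS = {v: k for k, v in CATEGORY_CODES.items()}


@dataclass(frozen=True)
class LandscapeSpec:
    """Dimensions and texture of a synthetic environmental stack."""

    n_rows: int
    n_cols: int
    n_layers: int = 2
    cell_size: float = 1.0
    autocorrelation_range: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.n_rows < 4 or self.n_cols < 4:
            raise ValueError("landscape must be at least 4x4 cells")
        if self.n_layers < 2:
            raise ValueError("at least 2 environmental layers are required")
        if self.autocorrelation_range < 1:
            raise ValueError("autocorrelation_range must be >= 1 cell")


@dataclass(frozen=True)
class SpeciesTruth:
    """Ground-truth Gaussian niche of a synthetic species.

    ``niche_center`` and ``niche_breadth`` are given per environmental layer
    (in the layers' standardized units); true suitability at a cell is the
    product of the per-layer Gaussian kernels, rescaled so its maximum over
    the landscape is 1.
    """

    niche_center: np.ndarray
    niche_breadth: np.ndarray
    prevalence_target: float = 0.2

    def __post_init__(self):
        c = np.atleast_1d(np.asarray(self.niche_center, dtype=float))
        b = np.atleast_1d(np.asarray(self.niche_breadth, dtype=float))
        if c.shape != b.shape:
            raise ValueError("niche_center and niche_breadth must have equal length")
        if np.any(b <= 0):
            raise ValueError("niche_breadth must be strictly positive")
        if not 0 < self.prevalence_target < 1:
            raise ValueError("prevalence_target must lie in (0, 1)")
        object.__setattr__(self, "niche_center", c)
        object.__setattr__(self, "niche_breadth", b)


@dataclass
class EnvStack:
    """A stack of single-band rasters sharing one grid."""

    grid: RasterGrid
    data: np.ndarray  # (n_layers, n_rows, n_cols), NaN at nodata
    names: list[str] = field(default_factory=list)

    @property
    def n_layers(self) -> int:
        return self.data.shape[0]

    def values_at(self, points: np.ndarray) -> np.ndarray:
        """(n_points, n_layers) matrix of layer values at point locations."""
        from .grid import raster_values_at

        return np.column_stack(
            [raster_values_at(self.data[k], self.grid, points) for k in range(self.n_layers)]
        )

    def valid_matrix(self) -> np.ndarray:
        """(n_valid_cells, n_layers) matrix over valid cells, row-major order."""
        m = self.grid.mask
        return np.column_stack([self.data[k][m] for k in range(self.n_layers)])


@dataclass
class ProtectionMap:
    """Per-cell protection category: SPA, SUA, IT or unprotected."""

    grid: RasterGrid
    codes: np.ndarray  # int array, one of CATEGORY_CODES.values()

    def category_mask(self, category: str | list[str]) -> np.ndarray:
        cats = [category] if isinstance(category, str) else list(category)
        wanted = [CATEGORY_CODES[c] for c in cats]
        return np.isin(self.codes, wanted) & self.grid.mask

    def counts(self) -> dict[str, int]:
        return {
            name: int(((self.codes == code) & self.grid.mask).sum())
            for name, code in CATEGORY_CODES.items()
        }


@dataclass
class BasinMap:
    """Contiguous basin partition of the valid cells plus its adjacency graph.

    ``labels`` holds basin ids 0..n_basins-1 (-1 on nodata cells); adjacency
    is the symmetric, irreflexive set of ordered basin-id pairs sharing at
    least one cell edge.
    """

    grid: RasterGrid
    labels: np.ndarray
    adjacency: frozenset  # of (int, int) ordered pairs, both orientations

    @property
    def n_basins(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def neighbors(self, basin: int) -> set[int]:
        return {b for a, b in self.adjacency if a == basin}


def make_env_stack(spec: LandscapeSpec) -> EnvStack:
    """Generate spatially autocorrelated, standardized environmental layers.

    Each layer is Gaussian-smoothed white noise (kernel scale equal to
    ``autocorrelation_range`` in cells) re-standardized to zero mean and unit
    variance over valid cells. Deterministic for a given seed.
    """
    rng = np.random.default_rng(spec.seed)
    grid = RasterGrid(spec.n_rows, spec.n_cols, cell_size=spec.cell_size)
    layers = np.empty((spec.n_layers, spec.n_rows, spec.n_cols))
    for k in range(spec.n_layers):
        noise = rng.standard_normal((spec.n_rows, spec.n_cols))
        smooth = ndimage.gaussian_filter(noise, sigma=spec.autocorrelation_range,
                                         mode="reflect")
        smooth -= smooth.mean()
        sd = smooth.std()
        if sd == 0:  # pathological but possible for tiny grids
            sd = 1.0
        layers[k] = smooth / sd
    names = [f"env_{k + 1:02d}" for k in range(spec.n_layers)]
    return EnvStack(grid=grid, data=layers, names=names)


def make_true_suitability(stack: EnvStack, truth: SpeciesTruth) -> np.ndarray:
    """True suitability raster: product of per-layer Gaussian kernels.

    suitability(cell) = prod_k exp(-((x_k - center_k) / breadth_k)^2 / 2),
    rescaled so the landscape maximum is 1.
    """
    if len(truth.niche_center) != stack.n_layers:
        raise ValueError(
            f"niche has {len(truth.niche_center)} dimensions but the stack has "
            f"{stack.n_layers} layers"
        )
    z = (stack.data - truth.niche_center[:, None, None]) / truth.niche_breadth[:, None, None]
    suit = np.exp(-0.5 * (z ** 2).sum(axis=0))
    suit[~stack.grid.mask] = np.nan
    peak = np.nanmax(suit)
    if peak > 0:
        suit = suit / peak
    return suit


def sample_occurrences(true_suit: np.ndarray, grid: RasterGrid, n: int, seed: int,
                       species: str = "species", replace: bool = True,
                       jitter: float = 0.25) -> pd.DataFrame:
    """Draw occurrence records with probability proportional to suitability.

    Points are placed at cell centers with a small uniform jitter (fraction of
    a cell). Each record carries a synthetic collection date drawn uniformly
    from 1900–2022 and a source tag.

    Returns a DataFrame with columns species, lon, lat, date, source.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    cols = ["species", "lon", "lat", "date", "source"]
    if n == 0:
        return pd.DataFrame(columns=cols)
    rng = np.random.default_rng(seed)
    suit = np.asarray(true_suit, dtype=float).copy()
    suit[~grid.mask] = 0.0
    suit[np.isnan(suit)] = 0.0
    flat = suit.ravel()
    total = flat.sum()
    if total <= 0:
        raise ValueError("suitability has no positive mass to sample from")
    n_positive = int((flat > 0).sum())
    if not replace and n > n_positive:
        raise ValueError(
            f"cannot draw {n} occurrences without replacement from "
            f"{n_positive} positive-suitability cells"
        )
    idx = rng.choice(flat.size, size=n, replace=replace, p=flat / total)
    rows, cells = np.divmod(idx, grid.n_cols)
    centers = np.array([grid.cell_center(r, c) for r, c in zip(rows, cells)])
    offs = rng.uniform(-jitter, jitter, size=(n, 2)) * grid.cell_size
    xy = centers + offs
    years = rng.integers(1900, 2023, size=n)
    months = rng.integers(1, 13, size=n)
    days = rng.integers(1, 29, size=n)
    dates = [f"{y:04d}-{m:02d}-{d:02d}" for y, m, d in zip(years, months, days)]
    return pd.DataFrame({
        "species": species,
        "lon": xy[:, 0],
        "lat": xy[:, 1],
        "date": dates,
        "source": "synthetic",
    })


def make_protection_map(grid: RasterGrid, fractions: dict[str, float],
                        block_size: int, seed: int) -> ProtectionMap:
    """Assign spatially clustered protection categories to grid blocks.

    The grid is tiled into axis-aligned ``block_size`` × ``block_size`` blocks;
    blocks are assigned whole to SPA, SUA or IT in a seeded random order until
    each category's requested cell fraction is reached, so realized fractions
    land within one block of the request. Remaining cells are unprotected.
    """
    fr = {k: float(fractions.get(k, 0.0)) for k in ("SPA", "SUA", "IT")}
    if any(v < 0 for v in fr.values()):
        raise ValueError("fractions must be non-negative")
    if sum(fr.values()) > 1 + 1e-12:
        raise ValueError("protection fractions must sum to at most 1")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    rng = np.random.default_rng(seed)
    codes = np.zeros(grid.shape, dtype=int)
    n_valid = grid.n_valid
    targets = {k: v * n_valid for k, v in fr.items()}
    assigned = {k: 0 for k in fr}
    n_br = -(-grid.n_rows // block_size)
    n_bc = -(-grid.n_cols // block_size)
    blocks = [(br, bc) for br in range(n_br) for bc in range(n_bc)]
    rng.shuffle(blocks)
    for br, bc in blocks:
        cat = next((k for k in ("SPA", "SUA", "IT")
                    if targets[k] > 0 and assigned[k] < targets[k]), None)
        if cat is None:
            break
        r0, c0 = br * block_size, bc * block_size
        sl = (slice(r0, min(r0 + block_size, grid.n_rows)),
              slice(c0, min(c0 + block_size, grid.n_cols)))
        free = (codes[sl] == 0) & grid.mask[sl]
        codes[sl][free] = CATEGORY_CODES[cat]
        assigned[cat] += int(free.sum())
    codes[~grid.mask] = 0
    return ProtectionMap(grid=grid, codes=codes)


def make_basins(grid: RasterGrid, n_basins: int, seed: int) -> BasinMap:
    """Partition valid cells into contiguous basins grown from random seeds.

    Basins are grown by multi-source breadth-first search over 4-neighbor
    edges, so every basin is 4-connected, basins are mutually exclusive and
    jointly exhaustive over valid cells. Adjacency lists basin pairs sharing
    at least one cell edge (symmetric, irreflexive).
    """
    n_valid = grid.n_valid
    if not 1 <= n_basins <= n_valid:
        raise ValueError("n_basins must lie between 1 and the number of valid cells")
    rng = np.random.default_rng(seed)
    labels = np.full(grid.shape, -1, dtype=int)
    valid_rc = np.argwhere(grid.mask)
    seed_idx = rng.choice(len(valid_rc), size=n_basins, replace=False)
    queue: deque[tuple[int, int]] = deque()
    for b, i in enumerate(seed_idx):
        r, c = valid_rc[i]
        labels[r, c] = b
        queue.append((r, c))
    while queue:
        r, c = queue.popleft()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if (0 <= rr < grid.n_rows and 0 <= cc < grid.n_cols
                    and grid.mask[rr, cc] and labels[rr, cc] == -1):
                labels[rr, cc] = labels[r, c]
                queue.append((rr, cc))
    pairs = set()
    right = (labels[:, :-1], labels[:, 1:])
    down = (labels[:-1, :], labels[1:, :])
    for a, b in (right, down):
        diff = (a != b) & (a >= 0) & (b >= 0)
        for u, v in zip(a[diff].ravel(), b[diff].ravel()):
            pairs.add((int(u), int(v)))
            pairs.add((int(v), int(u)))
    return BasinMap(grid=grid, labels=labels, adjacency=frozenset(pairs))
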