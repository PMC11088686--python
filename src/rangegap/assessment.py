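"""Protection-gap accounting and the randomization test of importance.

The analysis grid is overlaid on protection-category geometry (polygons or a
categorical raster): a cell belongs to a category only when at least 75% of
its area falls inside that category's units, otherwise it is unprotected.
Per species, the percentage of the modeled distribution inside each category
is computed together with the hierarchical cumulative series (strictest
first: SPA, then SPA+SUA, then SPA+SUA+IT); category percentages across
species are compared by one-way ANOVA. Conservation importance inside a
protection class is tested against chance by a Monte Carlo randomization:
draw as many cells as the class holds, uniformly from all valid cells, and
count how often the random mean importance reaches the observed one.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grid import RasterGrid
from .prioritize import ImportanceRaster, mean_importance
from .synth import CATEGORY_CODES, ProtectionMap

DEFAULT_COVERAGE_THRESHOLD = 0.75
DEFAULT_N_RAND = 10_000
CATEGORIES = ("SPA", "SUA", "IT")


def build_grid(extent: tuple[float, float, float, float], cell_size: float,
               study_polygon=None) -> RasterGrid:
    """Regular analysis lattice covering an extent, optionally masked.

    The lattice uses as many whole cells as needed to cover the extent
    (an extent smaller than one cell yields a single cell). With a study
    polygon, cells whose square lies entirely outside it are masked.
    """
    x_min, y_min, x_max, y_max = extent
    if not (x_max > x_min and y_max > y_min):
        raise ValueError("extent is degenerate")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    n_cols = max(1, int(np.ceil((x_max - x_min) / cell_size - 1e-9)))
    n_rows = max(1, int(np.ceil((y_max - y_min) / cell_size - 1e-9)))
    grid = RasterGrid(n_rows, n_cols, x_min=x_min, y_min=y_min, cell_size=cell_size)
    if study_polygon is not None:
        mask = np.zeros(grid.shape, dtype=bool)
        for r in range(n_rows):
            for c in range(n_cols):
                mask[r, c] = grid.cell_polygon(r, c).intersection(study_polygon).area > 0
        grid = RasterGrid(n_rows, n_cols, x_min=x_min, y_min=y_min,
                          cell_size=cell_size, mask=mask)
    return grid


def _fractions_from_polygons(grid: RasterGrid, polygons) -> dict[str, np.ndarray]:
    fracs = {cat: np.zeros(grid.shape) for cat in CATEGORIES}
    cell_area = grid.cell_size ** 2
    for cat, geom in polygons:
        if cat not in fracs:
            raise ValueError(f"unknown protection category {cat!r}")
        if not geom.is_valid:
            raise ValueError(f"invalid geometry for category {cat!r}")
        gx0, gy0, gx1, gy1 = geom.bounds
        for r in range(grid.n_rows):
            for c in range(grid.n_cols):
                cell = grid.cell_polygon(r, c)
                x0, y0, x1, y1 = cell.bounds
                if x1 < gx0 or x0 > gx1 or y1 < gy0 or y0 > gy1:
                    continue
                inter = cell.intersection(geom)
                if not inter.is_empty:
                    fracs[cat][r, c] += inter.area / cell_area
    return fracs


def _fractions_from_raster(grid: RasterGrid, fine: ProtectionMap) -> dict[str, np.ndarray]:
    centers = fine.grid.cell_centers()
    rc = grid.points_to_cells(centers)
    codes = fine.codes.ravel()
    fine_valid = fine.grid.mask.ravel()
    counts = {cat: np.zeros(grid.shape) for cat in CATEGORIES}
    cover = np.zeros(grid.shape)
    ok = (rc[:, 0] >= 0) & fine_valid
    for (r, c), code in zip(rc[ok], codes[ok]):
        cover[r, c] += 1
        for cat in CATEGORIES:
            if code == CATEGORY_CODES[cat]:
                counts[cat][r, c] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        return {cat: np.where(cover > 0, counts[cat] / cover, 0.0)
                for cat in CATEGORIES}


def classify_cells(grid: RasterGrid, categories,
                   coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD,
                   ) -> ProtectionMap:
    """Classify analysis cells by fractional coverage (the 75% rule).

    ``categories`` is either a list of (category, shapely geometry) pairs or
    a (possibly finer-grained) categorical `ProtectionMap`. A cell is
    assigned the category covering at least ``coverage_threshold`` of its
    area; cells where no category reaches the threshold are unprotected.
    With a threshold above 0.5 double assignment is geometrically
    impossible (asserted); at lower thresholds precedence is the most
    restrictive category first (SPA > SUA > IT).
    """
    if not 0 < coverage_threshold <= 1:
        raise ValueError("coverage_threshold must lie in (0, 1]")
    if isinstance(categories, ProtectionMap):
        fracs = _fractions_from_raster(grid, categories)
    else:
        fracs = _fractions_from_polygons(grid, categories)
    reach = np.stack([fracs[cat] >= coverage_threshold - 1e-9 for cat in CATEGORIES])
    if coverage_threshold > 0.5:
        assert reach.sum(axis=0).max() <= 1, (
            "two categories both cover more than half of one cell: "
            "inputs overlap")
    codes = np.zeros(grid.shape, dtype=int)
    for cat in reversed(CATEGORIES):  # apply precedence SPA > SUA > IT
        codes[reach[CATEGORIES.index(cat)]] = CATEGORY_CODES[cat]
    codes[~grid.mask] = 0
    return ProtectionMap(grid=grid, codes=codes)


def resample_binary(binary: np.ndarray, from_grid: RasterGrid,
                    to_grid: RasterGrid) -> np.ndarray:
    """Majority-rule resampling of a presence raster onto the analysis grid."""
    if from_grid.shape == to_grid.shape and from_grid.extent == to_grid.extent:
        return np.asarray(binary, dtype=bool) & to_grid.mask
    centers = from_grid.cell_centers()
    rc = to_grid.points_to_cells(centers)
    flat = np.asarray(binary, dtype=float).ravel()
    ok = (rc[:, 0] >= 0) & from_grid.mask.ravel()
    pres = np.zeros(to_grid.shape)
    tot = np.zeros(to_grid.shape)
    np.add.at(tot, (rc[ok, 0], rc[ok, 1]), 1)
    np.add.at(pres, (rc[ok, 0], rc[ok, 1]), flat[ok])
    out = np.zeros(to_grid.shape, dtype=bool)
    nonzero = tot > 0
    out[nonzero] = pres[nonzero] / tot[nonzero] > 0.5
    return out & to_grid.mask


def species_percentages(binary_range: np.ndarray, pmap: ProtectionMap) -> dict[str, float]:
    """Percentages of a species' presence cells per protection category.

    Returns pct_SPA / pct_SUA / pct_IT / pct_unprotected (summing to 100)
    plus the hierarchical cumulative series pct_SPA, pct_SPA_SUA,
    pct_SPA_SUA_IT.
    """
    pres = np.asarray(binary_range, dtype=bool) & pmap.grid.mask
    total = int(pres.sum())
    if total == 0:
        raise ValueError("species range has no presence cells on the analysis grid")
    pct = {}
    for cat in CATEGORIES + ("unprotected",):
        n_cat = int((pres & (pmap.codes == CATEGORY_CODES[cat])).sum())
        pct[f"pct_{cat}"] = 100.0 * n_cat / total
    pct["pct_SPA_SUA"] = pct["pct_SPA"] + pct["pct_SUA"]
    pct["pct_SPA_SUA_IT"] = pct["pct_SPA_SUA"] + pct["pct_IT"]
    return pct


def one_way_anova(groups: list[np.ndarray]) -> dict[str, float]:
    """Classical one-way ANOVA: F = (SSB/df_b) / (SSW/df_w), upper-tail p.

    Degenerate input with zero between- and within-group variance yields
    NaN with a warning rather than a silent zero.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 values")
    n_total = sum(len(g) for g in groups)
    k = len(groups)
    if n_total <= k:
        raise ValueError("total sample size must exceed the number of groups")
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n_total - k
    if ssw == 0 and ssb == 0:
        warnings.warn("ANOVA undefined: zero variance within and between groups",
                      stacklevel=2)
        return {"F": float("nan"), "df_between": df_b, "df_within": df_w,
                "p": float("nan")}
    if ssw == 0:
        return {"F": float("inf"), "df_between": df_b, "df_within": df_w, "p": 0.0}
    f_stat = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f_stat, df_b, df_w))
    return {"F": float(f_stat), "df_between": df_b, "df_within": df_w, "p": p}


@dataclass
class RandomizationResult:
    """Monte Carlo randomization test of mean importance inside a class."""

    category: str
    observed_mean: float
    randomized_mean: float
    n_randomizations: int
    n_ge: int          # raw count of draws with mean >= observed
    p: float
    exhaustive: bool = False

    def __str__(self) -> str:
        p_txt = f"< {1.0 / self.n_randomizations:g}" if self.n_ge == 0 else f"{self.p:g}"
        return (f"{self.category}: observed mean importance "
                f"{self.observed_mean:.4f} vs randomized {self.randomized_mean:.4f} "
                f"(p {p_txt}, n = {self.n_randomizations})")


def mc_randomization(importance: ImportanceRaster, target_cells: np.ndarray,
                     n_rand: int = DEFAULT_N_RAND, seed: int = 0,
                     category: str = "target",
                     exhaustive: bool = False) -> RandomizationResult:
    """Randomization test: is the class's mean importance higher than chance?

    The observed statistic is the mean importance rank over the target
    cells. Each randomization draws the same number of cells without
    replacement, uniformly from *all* valid cells, and records the mean;
    p = (number of draws with mean >= observed) / n_rand. With
    ``exhaustive=True`` every subset of that size is enumerated instead and
    p is exact (only sensible for tiny pools).
    """
    target = np.asarray(target_cells, dtype=bool)
    if not target.any():
        raise ValueError("target class is empty")
    observed = mean_importance(importance, target)
    pool = importance.rank_fraction[importance.grid.mask]
    k = int((target & importance.grid.mask).sum())
    if k > len(pool):
        raise ValueError("target class is larger than the valid-cell pool")
    if exhaustive:
        means = np.array([np.mean(c) for c in
                          itertools.combinations(pool.tolist(), k)])
        n_total = len(means)
    else:
        if n_rand < 1:
            raise ValueError("n_rand must be >= 1")
        rng = np.random.default_rng(seed)
        means = np.empty(n_rand)
        chunk = max(1, min(n_rand, int(2e6 / max(len(pool), 1)) or 1))
        done = 0
        while done < n_rand:
            m = min(chunk, n_rand - done)
            keys = rng.random((m, len(pool)))
            idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
            means[done:done + m] = pool[idx].mean(axis=1)
            done += m
        n_total = n_rand
    n_ge = int((means >= observed - 1e-12).sum())
    return RandomizationResult(category=category, observed_mean=observed,
                               randomized_mean=float(means.mean()),
                               n_randomizations=n_total, n_ge=n_ge,
                               p=n_ge / n_total, exhaustive=exhaustive)


# -- model-style wrapper ---------------------------------------------------

class ProtectionAssessment:
    """Gap analysis of species ranges against a protection map.

    Parameters
    ----------
    ranges : dict of str → ndarray
        Per-species binary presence rasters (on any grid; resampled to the
        analysis grid by majority rule).
    range_grid : RasterGrid
        Grid the ranges are defined on.
    pmap : ProtectionMap
        Analysis-grid protection categories (e.g. from `classify_cells`).
    importance : ImportanceRaster, optional
        Conservation-importance ranking for the randomization test.
    """

    def __init__(self, ranges: dict[str, np.ndarray], range_grid: RasterGrid,
                 pmap: ProtectionMap, importance: ImportanceRaster | None = None):
        if not ranges:
            raise ValueError("at least one species range is required")
        self.ranges = ranges
        self.range_grid = range_grid
        self.pmap = pmap
        self.importance = importance

    def fit(self, n_rand: int = DEFAULT_N_RAND, seed: int = 0) -> "GapReport":
        rows = []
        for sp in sorted(self.ranges):
            rng_grid = resample_binary(self.ranges[sp], self.range_grid,
                                       self.pmap.grid)
            rows.append({"species": sp, **species_percentages(rng_grid, self.pmap)})
        per_species = pd.DataFrame(rows)
        anova = None
        if len(per_species) >= 2:
            groups = [per_species[f"pct_{cat}"].to_numpy()
                      for cat in CATEGORIES + ("unprotected",)]
            anova = one_way_anova(groups)
        randomizations = []
        if (self.importance is not None
                and self.importance.grid.shape == self.pmap.grid.shape):
            rng = np.random.default_rng(seed)
            targets = [("SPA", ["SPA"]), ("SUA", ["SUA"]), ("IT", ["IT"]),
                       ("all_protected", list(CATEGORIES))]
            for name, cats in targets:
                mask = self.pmap.category_mask(cats) & self.importance.grid.mask
                if not mask.any():
                    continue
                randomizations.append(
                    mc_randomization(self.importance, mask, n_rand=n_rand,
                                     seed=int(rng.integers(2 ** 31)),
                                     category=name))
        return GapReport(per_species=per_species, anova=anova,
                         randomizations=randomizations, pmap=self.pmap)


@dataclass
class GapReport:
    """Per-species protection percentages, ANOVA and randomization tests."""

    per_species: pd.DataFrame
    anova: dict | None
    randomizations: list[RandomizationResult]
    pmap: ProtectionMap = field(repr=False, default=None)

    def randomization_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "category": r.category, "observed_mean": r.observed_mean,
            "randomized_mean": r.randomized_mean, "n_rand": r.n_randomizations,
            "n_ge": r.n_ge, "p": r.p,
        } for r in self.randomizations])

    def summary(self) -> str:
        lines = ["Protection gap report",
                 self.per_species.to_string(
                     index=False, float_format=lambda v: f"{v:.2f}")]
        if self.anova is not None:
            a = self.anova
            lines.append(
                f"ANOVA over category percentages: F({a['df_between']}, "
                f"{a['df_within']}) = {a['F']:.3f}, p = {a['p']:.4g}")
        for r in self.randomizations:
            lines.append(str(r))
        return "\n".join(lines)
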