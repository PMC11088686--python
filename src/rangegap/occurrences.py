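"""Occurrence record cleaning and spatial-autocorrelation thinning.

Raw records are screened by simple exclusion rules (missing coordinates,
missing or out-of-window dates, exact coordinate duplicates, points outside
the study extent). The surviving points are then thinned by an iterative
procedure driven by a Moran's correlogram on an environmental variable:
while the shortest-distance class shows significant positive autocorrelation,
one member of the closest pair of points is removed. Species retaining fewer
than five records are unusable for modeling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

MIN_POINTS = 5  # species need at least five occurrences to be modeled
YEAR_MIN, YEAR_MAX = 1900, 2022  # record search window


@dataclass
class OccurrenceSet:
    """Cleaned presence points for one species with provenance fields."""

    species: str
    records: pd.DataFrame  # columns: lon, lat, date, source

    def __len__(self) -> int:
        return len(self.records)

    @property
    def points(self) -> np.ndarray:
        return self.records[["lon", "lat"]].to_numpy(dtype=float)


def _valid_date(value) -> bool:
    ts = pd.to_datetime(value, errors="coerce")
    return pd.notna(ts) and YEAR_MIN <= ts.year <= YEAR_MAX


def clean_records(records: pd.DataFrame,
                  extent: tuple[float, float, float, float] | None = None,
                  ) -> tuple[dict[str, OccurrenceSet], pd.DataFrame]:
    """Apply the record exclusion rules and log every rejection.

    Rules, applied in order per record: ``missing_coordinates`` (lon or lat
    absent/non-finite), ``missing_date`` (absent, unparseable, or outside
    1900–2022), ``outside_extent`` (if an (x_min, y_min, x_max, y_max) extent
    is given), ``duplicate_coordinates`` (exact duplicate within a species;
    the first record is kept).

    Returns a dict species → OccurrenceSet plus the rejection log (one row
    per dropped record with its rule).
    """
    cols = ["species", "lon", "lat", "date", "source"]
    df = records.copy() if len(records) else pd.DataFrame(columns=cols)
    for c in cols:
        if c not in df.columns:
            df[c] = np.nan
    rejections = []
    kept_rows = []
    seen: dict[tuple[str, float, float], bool] = {}
    for idx, row in df.iterrows():
        lon, lat = row["lon"], row["lat"]
        rule = None
        if pd.isna(lon) or pd.isna(lat) or not np.isfinite([lon, lat]).all():
            rule = "missing_coordinates"
        elif not _valid_date(row["date"]):
            rule = "missing_date"
        elif extent is not None and not (
            extent[0] <= lon <= extent[2] and extent[1] <= lat <= extent[3]
        ):
            rule = "outside_extent"
        else:
            key = (str(row["species"]), float(lon), float(lat))
            if key in seen:
                rule = "duplicate_coordinates"
            else:
                seen[key] = True
        if rule is None:
            kept_rows.append(idx)
        else:
            rejections.append({**{c: row.get(c) for c in cols}, "rule": rule,
                               "record_index": idx})
    log = pd.DataFrame(rejections, columns=cols + ["rule", "record_index"])
    kept = df.loc[kept_rows]
    out = {
        str(sp): OccurrenceSet(species=str(sp),
                               records=g[["lon", "lat", "date", "source"]].reset_index(drop=True))
        for sp, g in kept.groupby("species", sort=True)
    }
    return out, log


def _morans_i_per_class(z: np.ndarray, pair_lists: list[tuple[np.ndarray, np.ndarray]],
                        denom: float) -> np.ndarray:
    n = len(z)
    out = np.empty(len(pair_lists))
    for k, (ii, jj) in enumerate(pair_lists):
        w = 2 * len(ii)  # binary weights, both orientations
        if w == 0 or denom == 0:
            out[k] = np.nan
        else:
            out[k] = (n / w) * 2 * np.sum(z[ii] * z[jj]) / denom
    return out


def morans_correlogram(points: np.ndarray, values: np.ndarray,
                       n_classes: int | None = None, n_perm: int = 999,
                       seed: int = 0) -> pd.DataFrame:
    """Moran's correlogram over equal-width classes of pairwise distance.

    Per distance class, Moran's I is computed with binary weights (a pair
    contributes iff its linear distance falls in the class); significance is
    a two-sided permutation test of the values over the points, with the
    identity permutation counted among the ``n_perm`` draws so p lies in
    [1/n_perm, 1].

    Values with zero variance make I undefined; such classes are reported
    with ``defined = False`` and p = 1 (not significant).

    Returns a DataFrame with columns class, d_min, d_max, n_pairs, morans_i,
    p, defined.
    """
    pts = np.asarray(points, dtype=float)
    vals = np.asarray(values, dtype=float)
    n = len(pts)
    if n < MIN_POINTS:
        raise ValueError(f"need at least {MIN_POINTS} points for a correlogram, got {n}")
    if not np.isfinite(vals).all():
        raise ValueError("values must be finite")
    d = pdist(pts)
    n_pairs_total = len(d)
    if n_classes is None:
        n_classes = max(2, int(np.ceil(np.log2(n_pairs_total) + 1)))  # Sturges
    d_max = d.max()
    if d_max == 0:  # all points coincident: a single degenerate class
        n_classes = 1
        edges = np.array([0.0, 1.0])
    else:
        edges = np.linspace(0.0, d_max, n_classes + 1)
    # assign each pair to a class (upper edge inclusive for the last class)
    cls = np.minimum(np.searchsorted(edges, d, side="right") - 1, n_classes - 1)
    cls[d == 0] = 0
    iu = np.triu_indices(n, k=1)
    pair_lists = []
    for k in range(n_classes):
        in_k = cls == k
        pair_lists.append((iu[0][in_k], iu[1][in_k]))

    z = vals - vals.mean()
    denom = float(np.sum(z ** 2))
    i_obs = _morans_i_per_class(z, pair_lists, denom)

    rng = np.random.default_rng(seed)
    count_ge = np.zeros(n_classes)
    if denom > 0:
        count_ge += 1  # identity permutation
        for _ in range(n_perm - 1):
            zp = rng.permutation(z)
            i_perm = _morans_i_per_class(zp, pair_lists, denom)
            with np.errstate(invalid="ignore"):
                count_ge += np.abs(i_perm) >= np.abs(i_obs)
        p = count_ge / n_perm
    else:
        p = np.ones(n_classes)
    defined = np.isfinite(i_obs) & (denom > 0)
    p = np.where(defined, p, 1.0)
    return pd.DataFrame({
        "class": np.arange(n_classes),
        "d_min": edges[:-1],
        "d_max": edges[1:],
        "n_pairs": [len(ii) for ii, _ in pair_lists],
        "morans_i": i_obs,
        "p": p,
        "defined": defined,
    })


def _drop_candidate(pts: np.ndarray) -> int:
    """Index to remove: the denser member of the closest pair (ties: lower index)."""
    dm = squareform(pdist(pts))
    np.fill_diagonal(dm, np.inf)
    i, j = np.unravel_index(np.argmin(dm), dm.shape)
    if i > j:
        i, j = j, i
    with np.errstate(divide="ignore"):
        inv = 1.0 / np.maximum(dm, 1e-12)
    inv[~np.isfinite(inv)] = 0.0
    dens_i, dens_j = inv[i].sum(), inv[j].sum()
    if dens_i > dens_j:
        return int(i)
    if dens_j > dens_i:
        return int(j)
    return int(i)  # tie: lower record index


def autocorr_filter(occ: OccurrenceSet, env_values: np.ndarray, alpha: float = 0.05,
                    seed: int = 0, n_classes: int | None = None,
                    n_perm: int = 999) -> OccurrenceSet:
    """Thin an occurrence set until its first distance class is non-significant.

    The correlogram is computed on ``env_values`` (one value per point; by
    convention the first principal component of the environmental stack at
    the point). While the shortest distance class with pairs shows
    significant autocorrelation at ``alpha``, the denser member of the
    closest pair of points is removed. Never thins below five points.

    The returned set is always a subset of the input.
    """
    if len(occ) < MIN_POINTS:
        raise ValueError(
            f"species {occ.species!r} has {len(occ)} records; at least "
            f"{MIN_POINTS} are required"
        )
    vals = np.asarray(env_values, dtype=float)
    if len(vals) != len(occ):
        raise ValueError("env_values must align with the occurrence records")
    keep = np.arange(len(occ))
    rng = np.random.default_rng(seed)
    while len(keep) > MIN_POINTS:
        sub_pts = occ.points[keep]
        table = morans_correlogram(sub_pts, vals[keep], n_classes=n_classes,
                                   n_perm=n_perm, seed=int(rng.integers(2 ** 31)))
        with_pairs = table[table["n_pairs"] > 0]
        if with_pairs.empty:
            break
        first = with_pairs.iloc[0]
        if (not first["defined"]) or first["p"] >= alpha:
            break
        keep = np.delete(keep, _drop_candidate(sub_pts))
    return OccurrenceSet(species=occ.species,
                         records=occ.records.iloc[keep].reset_index(drop=True))
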