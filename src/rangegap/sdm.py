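"""Per-species suitability modeling and confusion-matrix evaluation.

Four learner families map environmental axes to a suitability surface in
[0, 1]: a regularized log-linear density-ratio model with quadratic features
(maximum entropy), a bagged-tree classifier (random forest), a kernel margin
classifier with probability calibration (support vector), and a Gaussian
class-conditional Bayes classifier. Density-ratio learners (max entropy,
Gaussian Bayes) contrast presences against background points; the
discriminative learners (random forest, support vector) require absence data
and are trained against pseudo-absences placed outside the presences'
environmental envelope.

Evaluation neglects true negatives where the Jaccard index is concerned:
the binarization threshold is the one maximizing TP / (TP + FP + FN) on the
held-out points, which penalizes omission and commission symmetrically
without rewarding large true-negative counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from sklearn.svm import SVC

from .grid import RasterGrid
from .environment import PcaStack
from .occurrences import OccurrenceSet

LEARNERS = ("max_entropy", "random_forest", "support_vector", "gaussian_bayes")
#: learners trained against background points rather than pseudo-absences
BACKGROUND_LEARNERS = frozenset({"max_entropy", "gaussian_bayes"})

DEFAULT_N_PSEUDO = 50
DEFAULT_N_BACKGROUND = 10_000
CHESSBOARD_MIN_POINTS = 30  # strictly more points than this → chessboard


class UndefinedMetricWarning(UserWarning):
    """A confusion-matrix metric had an empty class and is reported as NaN."""


@dataclass
class ContrastPoints:
    """Pseudo-absence or background points used as the modeling contrast."""

    kind: str  # "pseudo_absence" | "background"
    points: np.ndarray  # (n, 2)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class Partition:
    """Train/test split of occurrence indices (chessboard or 70/30 random)."""

    scheme: str  # "chessboard" | "random_split"
    train: np.ndarray
    test: np.ndarray


@dataclass
class FittedModel:
    """One learner's suitability surface plus its evaluation."""

    learner_id: str
    suitability: np.ndarray      # (n_rows, n_cols) in [0, 1], NaN at nodata
    threshold: float
    metrics: dict = field(default_factory=dict)  # auc, tss, jaccard, sensitivity, specificity


def envelope_pseudo_absences(presence_env: np.ndarray, env: PcaStack,
                             n: int = DEFAULT_N_PSEUDO, seed: int = 0) -> ContrastPoints:
    """Place pseudo-absences outside the presences' environmental envelope.

    The envelope is the per-axis [min, max] of the presence values; candidate
    cells fall outside it on at least one axis (deemed unsuitable), and ``n``
    of them are sampled uniformly without replacement. If fewer than ``n``
    cells qualify, all of them are returned with a warning.
    """
    pres = np.asarray(presence_env, dtype=float)
    if len(pres) < 5:
        raise ValueError("need at least 5 presences to define an envelope")
    if not np.isfinite(pres).all():
        raise ValueError("presence environmental values must be finite")
    lo = pres.min(axis=0)
    hi = pres.max(axis=0)
    cells = env.valid_matrix()
    outside = ((cells < lo) | (cells > hi)).any(axis=1)
    centers = env.grid.cell_centers().reshape(env.grid.n_rows, env.grid.n_cols, 2)
    candidate_xy = centers[env.grid.mask][outside]
    rng = np.random.default_rng(seed)
    if len(candidate_xy) < n:
        warnings.warn(
            f"only {len(candidate_xy)} cells fall outside the environmental "
            f"envelope; requested {n} pseudo-absences", stacklevel=2)
        chosen = candidate_xy
    else:
        idx = rng.choice(len(candidate_xy), size=n, replace=False)
        chosen = candidate_xy[idx]
    return ContrastPoints(kind="pseudo_absence", points=np.asarray(chosen, dtype=float))


def sample_background(grid: RasterGrid, n: int = DEFAULT_N_BACKGROUND,
                      seed: int = 0) -> ContrastPoints:
    """Sample background points uniformly over the study area's valid cells.

    Draws are without replacement while ``n`` does not exceed the number of
    valid cells, and with replacement otherwise.
    """
    if grid.n_valid < 1:
        raise ValueError("grid has no valid cells")
    rng = np.random.default_rng(seed)
    centers = grid.cell_centers().reshape(grid.n_rows, grid.n_cols, 2)[grid.mask]
    replace = n > len(centers)
    idx = rng.choice(len(centers), size=n, replace=replace)
    return ContrastPoints(kind="background", points=centers[idx])


def partition_points(occ: OccurrenceSet, grid: RasterGrid, seed: int = 0,
                     chess_block: int = 2) -> Partition:
    """Split occurrences for evaluation: chessboard if > 30 points, else 70/30.

    The chessboard scheme aggregates grid cells into ``chess_block``-sized
    blocks colored by (row + col) parity; points on black blocks train the
    model and points on white blocks evaluate it. Smaller samples get a
    seeded random 70/30 split with at least one test point. If a chessboard
    split would leave either side empty it falls back to the random split.
    """
    pts = occ.points
    n = len(pts)
    if n < 5:
        raise ValueError("need at least 5 points to partition")
    rng = np.random.default_rng(seed)
    if n > CHESSBOARD_MIN_POINTS:
        rc = grid.points_to_cells(pts)
        if (rc[:, 0] >= 0).all():
            parity = ((rc[:, 0] // chess_block) + (rc[:, 1] // chess_block)) % 2
            train = np.nonzero(parity == 0)[0]
            test = np.nonzero(parity == 1)[0]
            if len(train) and len(test):
                return Partition(scheme="chessboard", train=train, test=test)
    n_test = max(1, int(round(0.3 * n)))
    perm = rng.permutation(n)
    return Partition(scheme="random_split", train=perm[n_test:], test=perm[:n_test])


def _build_estimator(learner_id: str, seed: int):
    if learner_id == "max_entropy":
        return make_pipeline(
            PolynomialFeatures(degree=2, include_bias=False),
            StandardScaler(),
            LogisticRegression(C=1.0, max_iter=2000),
        )
    if learner_id == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if learner_id == "support_vector":
        return make_pipeline(
            StandardScaler(),
            SVC(kernel="rbf", probability=True, random_state=seed),
        )
    if learner_id == "gaussian_bayes":
        return QuadraticDiscriminantAnalysis(reg_param=1e-3)
    raise ValueError(f"unknown learner_id {learner_id!r}; expected one of {LEARNERS}")


def fit_learner(learner_id: str, train_presence_env: np.ndarray,
                contrast_env: np.ndarray, env: PcaStack, seed: int = 0) -> np.ndarray:
    """Fit one learner and score every valid cell, rescaled to [0, 1].

    Presences (label 1) are contrasted against the supplied contrast points
    (label 0); the fitted class-1 probability over the grid is min-max
    rescaled, a monotone transform that leaves rank-based evaluation
    unchanged. A constant score surface maps to 0.5 everywhere.
    """
    pres = np.asarray(train_presence_env, dtype=float)
    contr = np.asarray(contrast_env, dtype=float)
    if len(pres) == 0 or len(contr) == 0:
        raise ValueError("training presences and contrast points must be non-empty")
    x = np.vstack([pres, contr])
    if len(np.unique(x, axis=0)) < 2:
        raise ValueError("degenerate training data: a single unique environment vector")
    y = np.concatenate([np.ones(len(pres)), np.zeros(len(contr))])
    est = _build_estimator(learner_id, seed)
    with warnings.catch_warnings():
        # SVC(probability=True) is deprecated upstream but remains the
        # stable way to calibrate margins at the tiny class sizes used here
        warnings.simplefilter("ignore", FutureWarning)
        est.fit(x, y)
    cells = env.valid_matrix()
    scores = est.predict_proba(cells)[:, 1]
    lo, hi = scores.min(), scores.max()
    scaled = np.full_like(scores, 0.5) if hi == lo else (scores - lo) / (hi - lo)
    out = np.full(env.grid.shape, np.nan)
    out[env.grid.mask] = scaled
    return out


# -- confusion-matrix evaluation ------------------------------------------

def confusion_counts(pres_scores: np.ndarray, abs_scores: np.ndarray,
                     threshold: float) -> dict[str, int]:
    """TP/FP/FN/TN counts: presence is predicted where score >= threshold."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    p = np.asarray(pres_scores, dtype=float)
    a = np.asarray(abs_scores, dtype=float)
    if len(p) == 0 and len(a) == 0:
        raise ValueError("test sets are empty")
    return {
        "TP": int((p >= threshold).sum()),
        "FN": int((p < threshold).sum()),
        "FP": int((a >= threshold).sum()),
        "TN": int((a < threshold).sum()),
    }


def tss(counts: dict[str, int]) -> float:
    """True Skill Statistic: sensitivity + specificity − 1, in [−1, 1]."""
    pos = counts["TP"] + counts["FN"]
    neg = counts["TN"] + counts["FP"]
    if pos == 0 or neg == 0:
        warnings.warn("TSS undefined: an observed class is empty",
                      UndefinedMetricWarning, stacklevel=2)
        return float("nan")
    return counts["TP"] / pos + counts["TN"] / neg - 1.0


def jaccard(counts: dict[str, int]) -> float:
    """Jaccard index TP / (TP + FP + FN); ignores true negatives."""
    denom = counts["TP"] + counts["FP"] + counts["FN"]
    if denom == 0:
        warnings.warn("Jaccard undefined: no positives observed or predicted",
                      UndefinedMetricWarning, stacklevel=2)
        return float("nan")
    return counts["TP"] / denom


def auc(pres_scores: np.ndarray, abs_scores: np.ndarray) -> float:
    """Rank-based AUC: probability a presence outscores an absence."""
    p = np.asarray(pres_scores, dtype=float)
    a = np.asarray(abs_scores, dtype=float)
    if len(p) == 0 or len(a) == 0:
        warnings.warn("AUC undefined: a test class is empty",
                      UndefinedMetricWarning, stacklevel=2)
        return float("nan")
    y = np.concatenate([np.ones(len(p)), np.zeros(len(a))])
    return float(roc_auc_score(y, np.concatenate([p, a])))


def select_threshold(pres_scores: np.ndarray, abs_scores: np.ndarray) -> float:
    """Threshold maximizing the Jaccard index over held-out scores.

    Candidates are the sorted unique scores of the test points; ties are
    broken toward the lower threshold (the less exclusive map).
    """
    p = np.asarray(pres_scores, dtype=float)
    a = np.asarray(abs_scores, dtype=float)
    candidates = np.unique(np.concatenate([p, a]))
    best_t, best_j = candidates[0], -1.0
    for t in candidates:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UndefinedMetricWarning)
            j = jaccard(confusion_counts(p, a, t))
        if np.isnan(j):
            continue
        if j > best_j:  # strict: keeps the lowest threshold on ties
            best_j, best_t = j, t
    return float(best_t)


def evaluate_model(suitability: np.ndarray, grid: RasterGrid,
                   test_presences: np.ndarray, test_absences: np.ndarray,
                   learner_id: str = "") -> FittedModel:
    """Select the Jaccard-optimal threshold and compute all metrics."""
    from .grid import raster_values_at

    p = raster_values_at(suitability, grid, test_presences)
    a = raster_values_at(suitability, grid, test_absences)
    p = p[np.isfinite(p)]
    a = a[np.isfinite(a)]
    if len(p) == 0 or len(a) == 0:
        raise ValueError("test presences/absences do not fall on valid cells")
    thr = select_threshold(p, a)
    counts = confusion_counts(p, a, thr)
    pos = counts["TP"] + counts["FN"]
    neg = counts["TN"] + counts["FP"]
    metrics = {
        "auc": auc(p, a),
        "tss": tss(counts),
        "jaccard": jaccard(counts),
        "sensitivity": counts["TP"] / pos if pos else float("nan"),
        "specificity": counts["TN"] / neg if neg else float("nan"),
    }
    return FittedModel(learner_id=learner_id, suitability=suitability,
                       threshold=thr, metrics=metrics)
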