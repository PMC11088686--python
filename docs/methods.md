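# Methods

This note records the scientific choices behind `rangegap`: the models and
procedures, their assumptions, the parameters that matter, what the
synthetic-data generator does and does not emulate, and the numerical
decisions taken where the design was genuinely open.

## Spatial frame

All analyses run on a regular lattice of square cells (`RasterGrid`) with an
optional validity mask. The grid is treated as planar and equal-area: the
latitude-dependent distortion of a real geographic grid (e.g. a 0.05° cell
near the equator vs. at 10°S) is deliberately ignored, so percentages are
cell-count shares, not area-weighted shares. Rasters are exchanged as
plain-text ESRI ASCII grids and category maps additionally as GeoJSON
polygons; values are serialized with `repr` so identical analyses produce
byte-identical files.

## Synthetic landscapes

`synth` generates every input the pipeline needs, with known truth:

- **Environmental layers** are Gaussian-smoothed white noise. The kernel
  sigma equals `autocorrelation_range` (in cells), the simplest mechanism
  that gives controllable spatial autocorrelation; each layer is
  re-standardized to zero mean, unit variance over valid cells, so niche
  parameters are expressed in landscape standard deviations.
- **Species truth** is a product-Gaussian niche:
  `s(x) = Π_k exp(−((x_k − c_k)/b_k)² / 2)`, rescaled so the landscape
  maximum is 1. Breadth `b` is in layer SD units; `b ≈ 0.5` is a strongly
  specialized species, `b ≈ 0.8` (the generator default) a moderate
  specialist. Defaults elsewhere: occurrence samples of 80 records per
  species, 40×40-cell landscapes with 4 layers and autocorrelation range 5 —
  sizes at which every stage's behavior is visible without heavy compute.
- **Occurrences** are drawn with probability proportional to true
  suitability, jittered inside the cell, and stamped with a synthetic
  collection date uniform over 1900–2022 (to exercise the date-window
  cleaning rule) and a source tag. Real-world sampling bias along roads and
  rivers is *not* emulated; passing tests therefore demonstrate correctness
  of the machinery, not robustness to biased sampling.
- **Protection maps** assign whole square blocks (default 4×4 cells) to SPA,
  SUA or IT in a seeded random order until each category's requested cell
  fraction is met, so realized fractions land within one block of the
  request. Blocks make the categories spatially clustered, which is what the
  randomization test's behavior depends on; real protected-area geometry is
  more complex but the clustering scale is the relevant property.
- **Basins** grow from random seed cells by multi-source BFS over rook
  (4-neighbor) edges, yielding contiguous, exhaustive, mutually exclusive
  patches plus an edge-sharing adjacency graph.

## Occurrence cleaning and thinning

Cleaning applies, per record and in order: missing/non-finite coordinates;
missing, unparseable or out-of-window dates (window 1900–2022); outside the
study extent; exact coordinate duplicates (first record kept). Every
rejection is logged with its rule. Species with fewer than five surviving
records are unusable for modeling.

Thinning is driven by a Moran's correlogram on an environmental variable at
the points — by convention the first principal component of the stack, since
environmental autocorrelation is what inflates SDM performance estimates.
Distance classes are equal-width bins of pairwise linear distance (Sturges'
rule on the pair count by default); Moran's I per class uses binary weights,
and significance is a two-sided permutation test of the values over the
points. The identity permutation is counted among the `n_perm` draws, so
p-values live in `[1/n_perm, 1]`. While the shortest class with pairs is
significant at `alpha` (default 0.05), the algorithm removes one member of
the closest pair — the one with the higher inverse-distance density (ties:
the lower record index), which is deterministic and aggressive on clusters —
and never thins below five points. Zero-variance values make I undefined;
such classes are flagged and treated as non-significant rather than
silently zero.

## Predictor reduction

PCA is computed on the cell-wise covariance of the (already standardized)
layers over valid cells — equivalent to correlation PCA, matching the
multicollinearity-reduction purpose. The minimal set of leading axes with
cumulative explained variance ≥ `variance_target` (default 0.95) is
retained, and the component *scores* are used as model predictors. Each
axis's sign is fixed so its largest-magnitude loading is positive, making
outputs deterministic. Reconstruction from the retained axes has
squared-Frobenius relative error equal to the discarded variance fraction;
this is asserted in tests.

## Suitability models

Four learner families sit behind one contract (environment vectors → scores,
monotone min–max rescaled to [0, 1] over the grid; a constant surface maps
to 0.5):

| learner | backend | training contrast |
|---|---|---|
| `max_entropy` | L2-regularized logistic regression on degree-2 polynomial features (the classic linear+quadratic maximum-entropy feature set) | 10,000 background points |
| `gaussian_bayes` | quadratic discriminant analysis (Gaussian class-conditionals, `reg_param = 1e-3`) | 10,000 background points |
| `random_forest` | 100-tree random forest | 50 pseudo-absences |
| `support_vector` | RBF SVC with probability calibration | 50 pseudo-absences |

Pseudo-absences are cell centers sampled uniformly among cells falling
outside the per-axis [min, max] envelope of the training presences — i.e.
environments the species was never observed in. Background points are
uniform over valid cells (without replacement while the budget allows,
with replacement beyond).

Evaluation: species with more than 30 records get a chessboard block split
(blocks of 2 cells, colored by block-coordinate parity; black trains, white
tests — falling back to the random split if either color is empty), others
a seeded random 70/30 split with at least one test point. The field's usual
protocol leaves the evaluation absences unspecified; here the
pseudo-absence set is split 70/30 alongside the presences, and all learners
are scored against the same held-out presences and held-out pseudo-absences.
The binarization threshold is the held-out score (candidates: the unique
test-point scores; ties toward the lower threshold) maximizing the Jaccard
index `TP/(TP+FP+FN)`. TSS, AUC, sensitivity and specificity are reported
alongside; metrics with an empty class are NaN with a warning, never a
silent zero.

A note on score geometry: bagged trees produce exactly tied score plateaus
wherever all trees agree, so rank statistics computed against a smooth
gradient are capped by tie-midranking (≈ √3/2 for a pure step) even when the
surface is perfectly monotone. This is a property of tree ensembles, not a
defect of the fit, and the test suite accounts for it.

## Ensemble and spatial constraint

A model enters the ensemble iff its Jaccard value strictly exceeds the mean
Jaccard across the species' models (all models enter when all are tied).
The gate reads "Jaccard" as the *performance* value, not the cutoff — gating
on cutoffs would reward arbitrary score scalings. Included suitabilities are
averaged cell-wise; the ensemble threshold is the mean of the included
models' thresholds (re-optimizing on the ensemble surface would leak test
information into the final map), and the binary map is
`mean suitability ≥ threshold`.

The spatial constraint prunes overprediction: a basin is *predicted* if it
contains ≥ 1 presence cell; seed basins are predicted basins with ≥ 1
occurrence; the retained set is the seeds plus all predicted basins
reachable from a seed through chains of edge-adjacent predicted basins
(diagonal contact does not connect). Presence cells outside retained basins
are zeroed. The operation is idempotent and never adds cells.

## Prioritization

Cells are ranked by greedy core-area removal — a defined, reproducible
stand-in for the Zonation algorithm, chosen for its complementarity/
irreplaceability behavior; no claim of bit-compatibility with any Zonation
release is made. At each step the cell minimizing
`δ(cell) = max_s w_s · v_s(cell) / V_s` is removed, where `v_s` is species
s's value in the cell and `V_s` its total over the cells still present.
Remaining totals are recomputed from the surviving cells at every step so a
species' last remaining cell scores δ exactly `w_s` (no floating-point
drift), and ties break toward the lower flat cell index. Removal position
p of N defines the importance rank p/N; ranks are a bijection onto
{1/N, …, 1}. Inputs may be binary ranges (the pipeline default) or
continuous suitabilities. Exact one-cell-at-a-time removal is used — no
batching — which is O(N²·S) and entirely affordable at the grid sizes this
package targets (≈ 2 s at N = 1600, S = 3).

## Protection assessment

The analysis grid is classified by fractional coverage: per cell and
category, the covered fraction comes from polygon intersection areas
(shapely) or from the share of finer raster cells; the cell takes the
category covering ≥ 75% of it, else it is unprotected. With a threshold
above 0.5 double assignment is geometrically impossible (asserted); for
configurable thresholds ≤ 0.5, precedence is most-restrictive-first
(SPA > SUA > IT). Species ranges on a different grid are resampled by
majority rule.

Per species: `pct_X = 100 · (presence cells in X) / (presence cells)` for
X ∈ {SPA, SUA, IT, unprotected}, plus the hierarchical cumulative series
(SPA; SPA+SUA; SPA+SUA+IT = 100 − unprotected). One-way ANOVA compares the
four category percentage groups with species as replicates; no arcsine or
logit transform is applied. The classical F statistic and F-distribution
upper tail are computed directly (cross-checked against
`scipy.stats.f_oneway` in tests).

The randomization test draws, for each protection class, as many cells as
the class holds — uniformly *without* replacement from all valid cells,
protected and unprotected alike — records each draw's mean importance, and
reports `p = #(draw mean ≥ observed mean) / n_draws` (default 10,000 draws).
A raw count of 0 is kept as p = 0 with the textual report showing
`< 1/n_draws`. For tiny pools an exhaustive mode enumerates every subset and
gives the exact p.

## Determinism

Every stochastic step takes a seed; composite operations derive sub-seeds
from one master seed via `numpy.random.default_rng`. The CLI chain run twice
with one seed produces byte-identical CSV/ASC/GeoJSON/YAML outputs, which
the test suite asserts file-by-file.

## Known limitations

- Equal-area planar grid; no latitude weighting of percentages.
- Occurrence generation has no detection or accessibility bias, so the
  thinning step is exercised on environmental autocorrelation only.
- The greedy prioritizer is a stand-in: results will differ from any
  specific Zonation variant and settings.
- The Gaussian–Bayes learner is an interpretation of a loosely specified
  family; it is implemented as Gaussian class-conditional discrimination
  against background.
- The ensemble averages suitabilities before binarization; averaging binary
  maps is not offered.
- The randomization pool includes all valid cells; restricting the pool to
  unprotected cells would test a different (conditional) hypothesis.
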