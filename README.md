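# rangegap

Ensemble species distribution modeling and protected-area gap analysis on
gridded landscapes, with conservation prioritization and a Monte Carlo
randomization test of how much conservation importance falls inside each
protection class.

## The problem

Conservation assessments routinely need to answer: *how much of each
species' distribution is covered by strict protection units (SPA),
sustainable-use units (SUA), and indigenous lands (IT), and are the
protected cells actually the important ones?* Occurrence data are sparse and
spatially biased, so distributions are estimated with species distribution
models (SDMs) before the overlay. `rangegap` implements that full chain as a
tested, reusable library plus CLI, exercisable end to end on synthetic
landscapes with known ground truth:

1. **Occurrence preparation** — exclusion rules (missing coordinates or
   dates, exact duplicates, out-of-extent points) and iterative spatial
   thinning driven by a Moran's correlogram on an environmental variable,
   removing points until the shortest-distance class is no longer
   significantly autocorrelated.
2. **Predictor reduction** — PCA of the standardized environmental stack,
   retaining the leading axes whose cumulative explained variance ≥ 95%.
3. **SDM ensemble** — four learners (maximum entropy, random forest,
   support vector machine, Gaussian–Bayes). Density-ratio learners contrast
   presences with 10,000 background points; discriminative learners with 50
   pseudo-absences placed outside the presences' environmental envelope.
   Evaluation uses a chessboard spatial block split for species with more
   than 30 records, otherwise a random 70/30 split. The binarization
   threshold maximizes the Jaccard index
   `J = TP / (TP + FP + FN)` on held-out points — a metric that, unlike
   TSS (`sensitivity + specificity − 1`), neglects true negatives.
   The ensemble averages the suitability of the learners whose Jaccard
   performance beats the across-learner mean, and the binary range is pruned
   to drainage basins connected, through predicted basins, to basins holding
   occurrence records.
4. **Prioritization** — a greedy core-area cell-removal ranking (a defined,
   reproducible stand-in for Zonation): repeatedly delete the cell
   minimizing `δ(cell) = max_s w_s · v_s(cell) / V_s(remaining)`, so
   irreplaceable cells of restricted species are removed last. The removal
   order maps the N cells onto importance ranks {1/N, …, 1}.
5. **Gap analysis** — a regular analysis grid is classified by the 75%
   coverage rule (a cell belongs to a category only if ≥ 75% of its area is
   inside that category's units, otherwise it is unprotected); per-species
   percentages per category, the hierarchical cumulative series
   SPA → SPA+SUA → SPA+SUA+IT, one-way ANOVA across categories, and a Monte
   Carlo randomization test (default 10,000 draws) comparing the mean
   importance of each class against equally sized random cell sets, with
   `p = #(random mean ≥ observed mean) / n_draws`.

The `synth` module generates every input with known truth: spatially
autocorrelated standardized environmental layers, species with Gaussian
niches, occurrences sampled proportionally to true suitability,
block-clustered protection maps and contiguous basin partitions.

## Worked example

```python
import numpy as np
import rangegap as rg

# 1. synthetic landscape with a known Gaussian niche
spec = rg.LandscapeSpec(n_rows=30, n_cols=30, n_layers=3,
                        autocorrelation_range=4, seed=1)
stack = rg.make_env_stack(spec)
truth = rg.SpeciesTruth(niche_center=[0.5, -0.3, 0.0],
                        niche_breadth=[0.6, 0.6, 0.6])
suit = rg.make_true_suitability(stack, truth)
records = rg.sample_occurrences(suit, stack.grid, 80, seed=2, species="sp01")

# 2. clean records and reduce the predictors
sets, log = rg.clean_records(records, extent=stack.grid.extent)
pcs = rg.pca_reduce(stack, variance_target=0.95)

# 3. ensemble SDM with the basin constraint
basins = rg.make_basins(stack.grid, n_basins=9, seed=3)
result = rg.EnsembleSDM(sets["sp01"], pcs, basins=basins).fit(seed=4)
print(result.summary())
```

```
Ensemble SDM results — species: sp01
  records: 80  partition: chessboard (44 train / 36 test)
  included learners: max_entropy, random_forest
  ensemble threshold: 0.2324
  retained basins: 8  presence cells: 320
species        learner  threshold    auc    tss  jaccard  sensitivity  specificity  included_in_ensemble
   sp01    max_entropy     0.0548 0.9630 0.8778   0.9189       0.9444       0.9333                  True
   sp01  random_forest     0.4100 0.9528 0.8111   0.8947       0.9444       0.8667                  True
   sp01 support_vector     0.2270 0.9463 0.7444   0.8718       0.9444       0.8000                 False
   sp01 gaussian_bayes     0.0264 0.9278 0.7556   0.8421       0.8889       0.8667                 False
   sp01       ensemble     0.2324 0.9722 0.8111   0.8947       0.9444       0.8667                  True
```

Only the two learners whose Jaccard value exceeds the four-learner mean
enter the ensemble; the ensemble threshold is the mean of their thresholds,
and the constrained range keeps the 8 basins reachable from occupied ones.

```python
# 4. protection gap analysis with the randomization test
pmap = rg.make_protection_map(stack.grid, {"SPA": 0.1, "SUA": 0.15, "IT": 0.2},
                              block_size=4, seed=5)
importance = rg.rank_cells(result.binary_range.astype(float)[None], stack.grid)
report = rg.ProtectionAssessment({"sp01": result.binary_range}, stack.grid,
                                 pmap, importance=importance).fit(n_rand=10_000,
                                                                  seed=6)
print(report.summary())
```

```
Protection gap report
species  pct_SPA  pct_SUA  pct_IT  pct_unprotected  pct_SPA_SUA  pct_SPA_SUA_IT
   sp01    14.06    15.62   20.31            50.00        29.69           50.00
SPA: observed mean importance 0.5544 vs randomized 0.5009 (p 0.0279, n = 10000)
SUA: observed mean importance 0.5141 vs randomized 0.5004 (p 0.2675, n = 10000)
IT: observed mean importance 0.4739 vs randomized 0.5008 (p 0.9274, n = 10000)
all_protected: observed mean importance 0.5051 vs randomized 0.5006 (p 0.3261, n = 10000)
```

Half of this species' modeled range is unprotected; SPA cells hold
significantly higher-than-random conservation importance (p ≈ 0.03) while IT
cells do not.

## Command-line pipeline

The same chain is available as deterministic, file-based stages:

```sh
rangegap synth --out run --seed 7 --rows 40 --cols 40 --species 3
rangegap prep --dir run --seed 7
rangegap pca --dir run
rangegap fit --dir run --seed 7
rangegap ensemble --dir run
rangegap prioritize --dir run
rangegap assess --dir run --seed 7
```

Re-running the chain with the same seed reproduces byte-identical outputs;
every stage records its parameters and seeds in `run/run_manifest.yaml`.

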