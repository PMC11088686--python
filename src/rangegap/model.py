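"""Per-species ensemble distribution model with a fit()/results interface.

`EnsembleSDM` bundles the full per-species modeling protocol — evaluation
partition, envelope pseudo-absences, background sampling, the four learners,
Jaccard-optimal thresholding, Jaccard-gated ensemble averaging and the basin
spatial constraint — behind a model object whose ``fit`` returns an
`SDMResults` carrying every per-learner surface, the ensemble, the
constrained range and a summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import sdm
from .ensemble import ConstrainedRange, EnsembleResult, ensemble, spatial_constraint
from .environment import PcaStack
from .occurrences import OccurrenceSet
from .sdm import FittedModel, Partition
from .synth import BasinMap


class EnsembleSDM:
    """Ensemble species distribution model for one species.

    Parameters
    ----------
    occurrences : OccurrenceSet
        Cleaned, thinned presence records.
    env : PcaStack
        Retained principal-component score surfaces used as predictors.
    basins : BasinMap, optional
        Basin partition; when given, the fitted binary range is pruned by
        the occurrence-connectivity constraint.
    learners : sequence of str
        Learner families to fit (default: all four).
    n_pseudo, n_background : int
        Contrast-point budgets (defaults 50 and 10,000).
    chess_block : int
        Block size (cells) of the chessboard evaluation partition used for
        species with more than 30 records.
    """

    def __init__(self, occurrences: OccurrenceSet, env: PcaStack,
                 basins: BasinMap | None = None,
                 learners: tuple[str, ...] = sdm.LEARNERS,
                 n_pseudo: int = sdm.DEFAULT_N_PSEUDO,
                 n_background: int = sdm.DEFAULT_N_BACKGROUND,
                 chess_block: int = 2):
        unknown = set(learners) - set(sdm.LEARNERS)
        if unknown:
            raise ValueError(f"unknown learners: {sorted(unknown)}")
        if len(occurrences) < 5:
            raise ValueError(
                f"species {occurrences.species!r} has fewer than 5 records")
        self.occurrences = occurrences
        self.env = env
        self.basins = basins
        self.learners = tuple(learners)
        self.n_pseudo = n_pseudo
        self.n_background = n_background
        self.chess_block = chess_block

    def fit(self, seed: int = 0) -> "SDMResults":
        """Run the full per-species protocol deterministically for a seed."""
        rng = np.random.default_rng(seed)
        sub = lambda: int(rng.integers(2 ** 31))  # noqa: E731

        part = sdm.partition_points(self.occurrences, self.env.grid, seed=sub(),
                                    chess_block=self.chess_block)
        pts = self.occurrences.points
        train_pts, test_pts = pts[part.train], pts[part.test]
        train_env = self.env.values_at(train_pts)
        test_ok = np.isfinite(self.env.values_at(test_pts)).all(axis=1)
        train_ok = np.isfinite(train_env).all(axis=1)
        train_env = train_env[train_ok]
        test_pts = test_pts[test_ok]

        pseudo = sdm.envelope_pseudo_absences(train_env, self.env,
                                              n=self.n_pseudo, seed=sub())
        background = sdm.sample_background(self.env.grid, n=self.n_background,
                                           seed=sub())
        # pseudo-absences are split 70/30 alongside the presences so every
        # learner is scored against the same held-out absence set
        n_pa = len(pseudo)
        perm = np.random.default_rng(sub()).permutation(n_pa)
        n_pa_test = max(1, int(round(0.3 * n_pa)))
        pa_test = pseudo.points[perm[:n_pa_test]]
        pa_train = pseudo.points[perm[n_pa_test:]]

        bg_env = self.env.values_at(background.points)
        bg_env = bg_env[np.isfinite(bg_env).all(axis=1)]
        pa_train_env = self.env.values_at(pa_train)
        pa_train_env = pa_train_env[np.isfinite(pa_train_env).all(axis=1)]

        models: list[FittedModel] = []
        for learner in self.learners:
            contrast = bg_env if learner in sdm.BACKGROUND_LEARNERS else pa_train_env
            surface = sdm.fit_learner(learner, train_env, contrast, self.env,
                                      seed=sub())
            models.append(sdm.evaluate_model(surface, self.env.grid, test_pts,
                                             pa_test, learner_id=learner))

        ens = ensemble(models)
        ens_eval = sdm.evaluate_model(ens.suitability, self.env.grid, test_pts,
                                      pa_test, learner_id="ensemble")
        # threshold stays the gated mean; the evaluation is recomputed at it
        from .grid import raster_values_at
        p = raster_values_at(ens.suitability, self.env.grid, test_pts)
        a = raster_values_at(ens.suitability, self.env.grid, pa_test)
        p, a = p[np.isfinite(p)], a[np.isfinite(a)]
        counts = sdm.confusion_counts(p, a, min(max(ens.threshold, 0.0), 1.0))
        ens_metrics = {
            "auc": sdm.auc(p, a),
            "tss": sdm.tss(counts),
            "jaccard": sdm.jaccard(counts),
            "sensitivity": counts["TP"] / max(counts["TP"] + counts["FN"], 1),
            "specificity": counts["TN"] / max(counts["TN"] + counts["FP"], 1),
        }

        constrained = None
        if self.basins is not None:
            constrained = spatial_constraint(ens.binary, self.basins,
                                             self.occurrences)
        return SDMResults(model=self, partition=part, models=models,
                          ensemble=ens, ensemble_metrics=ens_metrics,
                          constrained=constrained, seed=seed,
                          pseudo_absences=pseudo, background=background)


@dataclass
class SDMResults:
    """Fitted surfaces, thresholds and metrics for one species."""

    model: EnsembleSDM
    partition: Partition
    models: list[FittedModel]
    ensemble: EnsembleResult
    ensemble_metrics: dict
    constrained: ConstrainedRange | None
    seed: int
    pseudo_absences: object = None
    background: object = None

    @property
    def species(self) -> str:
        return self.model.occurrences.species

    @property
    def binary_range(self) -> np.ndarray:
        """Final presence/absence raster (constrained when basins were given)."""
        if self.constrained is not None:
            return self.constrained.binary
        return self.ensemble.binary

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.models:
            rows.append({"species": self.species, "learner": m.learner_id,
                         "threshold": m.threshold, **m.metrics,
                         "included_in_ensemble":
                             m.learner_id in self.ensemble.included_learners})
        rows.append({"species": self.species, "learner": "ensemble",
                     "threshold": self.ensemble.threshold,
                     **self.ensemble_metrics, "included_in_ensemble": True})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.metrics_frame()
        lines = [
            f"Ensemble SDM results — species: {self.species}",
            f"  records: {len(self.model.occurrences)}  "
            f"partition: {self.partition.scheme} "
            f"({len(self.partition.train)} train / {len(self.partition.test)} test)",
            f"  included learners: {', '.join(self.ensemble.included_learners)}",
            f"  ensemble threshold: {self.ensemble.threshold:.4f}",
        ]
        if self.constrained is not None:
            lines.append(
                f"  retained basins: {len(self.constrained.retained_basins)}  "
                f"presence cells: {int(self.binary_range.sum())}")
        with pd.option_context("display.width", 120):
            lines.append(df.to_string(index=False,
                                      float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)
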