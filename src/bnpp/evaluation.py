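"""Method-comparison machinery: ROC sweeps and simulation run summaries.

Scores from many scans are pooled into two groups — those of the true
(data-generating) models and those of all other models — and a threshold
sweep yields an ROC curve.  Posteriors are "higher is positive"; p-values
are "lower is positive".  The curve is the raw step function over observed
scores (no interpolation or convex hull).  The headline discovery figure
is the false-positive rate at full sensitivity: the fraction of false
models one must accept to flag every true model.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean

import numpy as np
from sklearn.metrics import roc_curve

from .datamodel import ModelSpec
from .discovery import ScanResult

HIGHER_IS_POSITIVE = "higher_is_positive"
LOWER_IS_POSITIVE = "lower_is_positive"


@dataclass(frozen=True)
class ROCCurve:
    """Threshold-sweep operating points from (0,0) to (1,1)."""

    points: tuple[tuple[float, float], ...]
    orientation: str

    @property
    def fpr(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def tpr(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


@dataclass(frozen=True)
class RunSummary:
    """Aggregate over many simulated datasets, one scan each.

    ``times_true_model_highest`` counts datasets whose top-ranked model is
    exactly the generating one; the averages pool the true model's
    posterior, the best-scoring false model's posterior, and all false
    models' posteriors across datasets.
    """

    n_datasets: int
    times_true_model_highest: int
    avg_posterior_true: float
    avg_posterior_best_false: float
    avg_posterior_all_false: float


def roc_from_scores(
    true_model_scores: list[float],
    false_model_scores: list[float],
    orientation: str = HIGHER_IS_POSITIVE,
) -> ROCCurve:
    """ROC curve from pooled true- and false-model scores.

    Every distinct score serves as an inclusive discovery threshold; for
    ``lower_is_positive`` (p-values) the comparison is inverted.
    """
    if not true_model_scores or not false_model_scores:
        raise ValueError("both score lists must be nonempty")
    if orientation not in (HIGHER_IS_POSITIVE, LOWER_IS_POSITIVE):
        raise ValueError(f"unknown orientation: {orientation!r}")
    scores = np.concatenate([true_model_scores, false_model_scores]).astype(float)
    labels = np.concatenate(
        [np.ones(len(true_model_scores)), np.zeros(len(false_model_scores))]
    )
    if orientation == LOWER_IS_POSITIVE:
        scores = -scores
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    points = [(float(x), float(y)) for x, y in zip(fpr, tpr)]
    if points[0] != (0.0, 0.0):
        points.insert(0, (0.0, 0.0))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return ROCCurve(points=tuple(points), orientation=orientation)


def fpr_at_full_sensitivity(curve: ROCCurve) -> float:
    """Smallest false-positive rate among operating points with TPR = 1."""
    candidates = [f for f, t in curve.points if t >= 1.0]
    return min(candidates)


def summarize_runs(
    per_dataset: list[tuple[ScanResult, ModelSpec]]
) -> RunSummary:
    """Pool per-dataset scans against their generating models."""
    if not per_dataset:
        raise ValueError("no datasets to summarize")
    highest = 0
    true_post: list[float] = []
    best_false: list[float] = []
    all_false: list[float] = []
    for result, true_model in per_dataset:
        models = {rec.model for rec in result.records}
        if true_model not in models:
            raise ValueError(f"true model {true_model} absent from scan")
        if result.records[0].model == true_model:
            highest += 1
        false_posts = [
            rec.posterior for rec in result.records if rec.model != true_model
        ]
        true_post.append(result.posterior_of(true_model))
        best_false.append(max(false_posts))
        all_false.extend(false_posts)
    return RunSummary(
        n_datasets=len(per_dataset),
        times_true_model_highest=highest,
        avg_posterior_true=fmean(true_post),
        avg_posterior_best_false=fmean(best_false),
        avg_posterior_all_false=fmean(all_false),
    )
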