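"""Validation arithmetic for cascade output against a reference assessment.

Provides the 3×3 confusion matrix, one-vs-rest sensitivity/specificity per
class, a concordance score between two classification sets, the per-step
classification histogram with distribution-difference statistics, and the
review-reduction fraction (share of episodes a screening run would exclude
from manual review as ``no change``).

The concordance score of the expert-corpus methodology is a single numeric
agreement measure in ``[0, 1]``; its exact weighting scheme is owned by the
corpus methodology and can be plugged in via the ``strategy`` argument.  The
shipped default is the plain agreement fraction, which satisfies the score's
contract (range ``[0, 1]``, 1 for identical classification vectors,
symmetric in its arguments).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .core import LABELS, NO_CHANGE, ClassificationResult

__all__ = [
    "IdMismatchError",
    "ConfusionMatrix3",
    "StepHistogram",
    "StepDeltaStats",
    "confusion_matrix",
    "class_metrics",
    "concordance_score",
    "step_distribution_stats",
    "review_reduction_fraction",
]

PairList = Sequence[Tuple[str, str]]


class IdMismatchError(ValueError):
    """The two classification sets do not cover the same episode ids."""


@dataclass(frozen=True)
class ConfusionMatrix3:
    """3×3 contingency counts: ``counts[predicted label][true label]``."""

    counts: Mapping[str, Mapping[str, int]]

    def __post_init__(self):
        counts = {
            p: {t: int(self.counts.get(p, {}).get(t, 0)) for t in LABELS} for p in LABELS
        }
        if any(v < 0 for row in counts.values() for v in row.values()):
            raise ValueError("confusion-matrix entries must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return sum(v for row in self.counts.values() for v in row.values())

    def predicted_total(self, label: str) -> int:
        return sum(self.counts[label].values())

    def truth_total(self, label: str) -> int:
        return sum(self.counts[p][label] for p in LABELS)

    def as_array(self) -> np.ndarray:
        """Counts as an array with rows = predicted, columns = truth (label order
        temporal correlation / no change / no assessment)."""
        return np.array([[self.counts[p][t] for t in LABELS] for p in LABELS])


def _align(predicted: PairList, truth: PairList) -> Tuple[List[str], List[str]]:
    pred_map = dict(predicted)
    truth_map = dict(truth)
    if len(pred_map) != len(predicted) or len(truth_map) != len(truth):
        raise IdMismatchError("duplicate episode ids in a classification set")
    missing_in_pred = sorted(set(truth_map) - set(pred_map))
    missing_in_truth = sorted(set(pred_map) - set(truth_map))
    if missing_in_pred or missing_in_truth:
        raise IdMismatchError(
            f"id sets differ; missing from predictions: {missing_in_pred}; "
            f"missing from truth: {missing_in_truth}"
        )
    ids = [i for i, _ in truth]
    return [pred_map[i] for i in ids], [truth_map[i] for i in ids]


def confusion_matrix(predicted: PairList, truth: PairList) -> ConfusionMatrix3:
    """Count episodes by their (predicted label, true label) pair.

    Both arguments are ``(episode_id, label)`` sequences over identical id
    sets; a mismatch raises :class:`IdMismatchError` listing the missing ids.
    """
    pred_labels, truth_labels = _align(predicted, truth)
    counts: Dict[str, Dict[str, int]] = {p: {t: 0 for t in LABELS} for p in LABELS}
    for p, t in zip(pred_labels, truth_labels):
        counts[p][t] += 1
    return ConfusionMatrix3(counts)


def class_metrics(cm: ConfusionMatrix3, label: str) -> Tuple[float, float]:
    """One-vs-rest sensitivity and specificity for one class.

    sensitivity = (episodes of this true class predicted as it)
                  / (episodes of this true class);
    specificity = (episodes of other true classes not predicted as it)
                  / (episodes of other true classes).

    A zero denominator yields ``nan`` for that metric.
    """
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}")
    tp = cm.counts[label][label]
    truth_pos = cm.truth_total(label)
    truth_neg = cm.total - truth_pos
    fp = cm.predicted_total(label) - tp
    sensitivity = tp / truth_pos if truth_pos else math.nan
    specificity = (truth_neg - fp) / truth_neg if truth_neg else math.nan
    return sensitivity, specificity


def concordance_score(
    predicted: PairList,
    truth: PairList,
    strategy: Optional[Callable[[Sequence[str], Sequence[str]], float]] = None,
) -> float:
    """Agreement score in ``[0, 1]`` between two classification sets.

    The default strategy is the plain agreement fraction.  A custom
    ``strategy`` (e.g. the partial-credit weighting of the expert-corpus
    methodology) receives the two aligned label vectors and must return a
    value in ``[0, 1]``.
    """
    pred_labels, truth_labels = _align(predicted, truth)
    if strategy is None:
        if not pred_labels:
            return 1.0
        agree = sum(p == t for p, t in zip(pred_labels, truth_labels))
        return agree / len(pred_labels)
    score = float(strategy(pred_labels, truth_labels))
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"concordance strategy returned {score!r}, outside [0, 1]")
    return score


@dataclass(frozen=True)
class StepHistogram:
    """Per-step classification counts over the 18 cascade steps.

    ``percentages`` are counts relative to the histogram total, rounded to
    2 decimals (the printing convention used when comparing step
    distributions).
    """

    counts: Mapping[int, int]

    def __post_init__(self):
        counts = {s: int(self.counts.get(s, 0)) for s in range(1, 19)}
        if any(v < 0 for v in counts.values()):
            raise ValueError("step counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_results(cls, results: Iterable[ClassificationResult]) -> "StepHistogram":
        """Histogram of the steps that classified each episode.

        Degenerate results (no cascade step) are not counted.
        """
        counts: Dict[int, int] = {}
        for r in results:
            if r.step is not None:
                counts[r.step] = counts.get(r.step, 0) + 1
        return cls(counts)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def percentage(self, step: int) -> float:
        if self.total == 0:
            return 0.0
        return round(100.0 * self.counts[step] / self.total, 2)


@dataclass(frozen=True)
class StepDeltaStats:
    """Summary of absolute per-step percentage differences."""

    mean: float
    sd: float
    min: float
    max: float


def step_distribution_stats(
    hist_a: StepHistogram,
    hist_b: StepHistogram,
    include_precheck: bool = False,
) -> StepDeltaStats:
    """Compare two step distributions by their per-step percentage deltas.

    Percentages are rounded to 2 decimals before differencing (matching the
    printed convention), then the mean, population SD, min and max of the
    absolute deltas are taken over steps 2–18 (step 1 is excluded unless the
    reference-range pre-check was enabled for both runs).
    """
    first_step = 1 if include_precheck else 2
    deltas = np.array(
        [
            abs(hist_a.percentage(step) - hist_b.percentage(step))
            for step in range(first_step, 19)
        ]
    )
    return StepDeltaStats(
        mean=float(deltas.mean()),
        sd=float(deltas.std(ddof=0)),
        min=float(deltas.min()),
        max=float(deltas.max()),
    )


def review_reduction_fraction(
    source: Union[ConfusionMatrix3, Iterable[Union[ClassificationResult, Tuple[str, str], str]]],
) -> float:
    """Fraction of episodes labeled ``no change``.

    In a screening setting these episodes are excluded from manual review, so
    this is the reduction of expert workload.  Accepts a confusion matrix
    (predicted marginal is used), classification results, ``(id, label)``
    pairs, or bare labels.
    """
    if isinstance(source, ConfusionMatrix3):
        total = source.total
        if total == 0:
            raise ValueError("empty confusion matrix")
        return source.predicted_total(NO_CHANGE) / total
    labels: List[str] = []
    for item in source:
        if isinstance(item, ClassificationResult):
            labels.append(item.label)
        elif isinstance(item, str):
            labels.append(item)
        else:
            labels.append(item[1])
    if not labels:
        raise ValueError("no classifications given")
    return labels.count(NO_CHANGE) / len(labels)
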