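"""Cluster-to-activity evaluation protocol.

Clustering is unsupervised; to score it against ground truth, each
cluster is mapped to the most frequent activity label among its
*labeled* members (majority vote — a proxy for asking the user what a
cluster is), evaluation segments are excluded from the vote, and any
segment in a cluster with no labeled members falls back to a designated
'other' label.  Accuracy and macro-averaged F1 are then computed over
the evaluation segments only.

Fold schemes (F folds, every fold serving as pivot, adjacency wrapping
modulo F):

* ``E1V1T62`` — evaluate on the pivot fold, validate on the next,
  train on the remaining F-2 (label-rich regime).
* ``T1V1E62`` — train on the pivot fold, validate on the next,
  evaluate on the remaining F-2 (label-poor regime; clusters not
  represented among the two labeled folds trigger the fallback, which
  is the mechanism behind this scheme's degradation at large K).

The clustering itself is transductive: the model is fit once on the
full corpus and only the vote/score fold roles change per pivot.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import f1_score

from .corpus import Corpus
from .dmm import FitResult, GibbsConfig, Hyperparameters, fit
from .errors import ConfigError

FALLBACK_LABEL = "other"


@dataclass
class FoldScheme:
    """Role assignment of F folds relative to a pivot fold i."""

    name: str
    F: int = 64

    def __post_init__(self) -> None:
        if self.name not in ("E1V1T62", "T1V1E62"):
            raise ConfigError(f"unknown fold scheme {self.name!r}")
        if self.F < 3:
            raise ConfigError("fold schemes need at least 3 folds")

    def roles(self, pivot: int) -> tuple[set[int], set[int], set[int]]:
        """(train, validation, evaluation) fold-index sets for a pivot."""
        if not 0 <= pivot < self.F:
            raise ConfigError(f"pivot {pivot} out of [0, {self.F})")
        nxt = (pivot + 1) % self.F
        rest = set(range(self.F)) - {pivot, nxt}
        if self.name == "E1V1T62":
            return rest, {nxt}, {pivot}
        return {pivot}, {nxt}, rest


@dataclass
class EvaluationResult:
    """Scores for one pivot: vote map, predictions, accuracy, macro-F1."""

    cluster_map: dict[int, str]
    predictions: dict[str, str]          # evaluation segment id -> predicted label
    accuracy: float
    macro_f1: float
    estimated_clusters: int
    fallback_count: int
    pivot: int | None = None


@dataclass
class CrossValidationResult:
    """Per-pivot results plus aggregate mean/sd of both scores."""

    per_pivot: list[EvaluationResult]
    mean_accuracy: float
    sd_accuracy: float
    mean_macro_f1: float
    sd_macro_f1: float
    fit_result: FitResult | None = field(default=None, repr=False)


def majority_vote_map(
    assignments: Sequence[int],
    labels: Sequence[str | None],
    labeled_ids: set[int],
) -> dict[int, str]:
    """Most frequent label per cluster, voting only over ``labeled_ids``.

    ``labeled_ids`` are positional segment indices (the train+validation
    members).  Clusters with no labeled member get no mapping.  Vote
    ties break to the alphabetically first label.
    """
    votes: dict[int, Counter] = {}
    for i in labeled_ids:
        if labels[i] is None:
            raise ConfigError(f"segment index {i} in the vote set has no label")
        votes.setdefault(int(assignments[i]), Counter())[labels[i]] += 1
    return {
        c: min((lab for lab, n in counter.items() if n == max(counter.values())))
        for c, counter in votes.items()
    }


def predict_labels(
    assignments: Sequence[int],
    cluster_map: Mapping[int, str],
    fallback: str = FALLBACK_LABEL,
) -> list[str]:
    """Mapped clusters predict their label; unmapped clusters predict ``fallback``."""
    return [cluster_map.get(int(k), fallback) for k in assignments]


def score(
    predictions: Sequence[str],
    truth: Sequence[str | None],
    eval_ids: Sequence[int],
) -> tuple[float, float]:
    """(accuracy, macro-F1) over the evaluation indices.

    Macro-F1 averages per-activity F1 over the set of activities
    present in the evaluation truth; an activity with no true and no
    predicted positives contributes F1 = 0.  A predicted label outside
    the truth set (e.g. the fallback) can only hurt, never help.
    """
    eval_ids = list(eval_ids)
    if not eval_ids:
        raise ConfigError("empty evaluation set")
    y_true = []
    y_pred = []
    for i in eval_ids:
        if truth[i] is None:
            raise ConfigError(f"evaluation segment index {i} has no label")
        y_true.append(truth[i])
        y_pred.append(predictions[i])
    accuracy = float(np.mean([t == p for t, p in zip(y_true, y_pred)]))
    classes = sorted(set(y_true))
    macro_f1 = float(f1_score(y_true, y_pred, labels=classes, average="macro", zero_division=0))
    return accuracy, macro_f1


def evaluate_pivot(
    corpus: Corpus,
    assignments: Sequence[int],
    scheme: FoldScheme,
    pivot: int,
    fallback: str = FALLBACK_LABEL,
) -> EvaluationResult:
    """Vote + predict + score one pivot of a fold scheme on a fixed clustering."""
    folds = corpus.folds()
    labels = corpus.labels()
    if any(f is None for f in folds):
        raise ConfigError("every segment needs a fold index for cross-validation")
    train, val, ev = scheme.roles(pivot)
    labeled_ids = {i for i, f in enumerate(folds) if f in train or f in val}
    eval_ids = [i for i, f in enumerate(folds) if f in ev]
    cluster_map = majority_vote_map(assignments, labels, labeled_ids)
    preds = predict_labels(assignments, cluster_map, fallback=fallback)
    accuracy, macro_f1 = score(preds, labels, eval_ids)
    fallback_count = sum(1 for i in eval_ids if int(assignments[i]) not in cluster_map)
    return EvaluationResult(
        cluster_map=cluster_map,
        predictions={corpus.segments[i].id: preds[i] for i in eval_ids},
        accuracy=accuracy,
        macro_f1=macro_f1,
        estimated_clusters=len(set(int(k) for k in assignments)),
        fallback_count=fallback_count,
        pivot=pivot,
    )


def cross_validate(
    corpus: Corpus,
    scheme: FoldScheme,
    hyper: Hyperparameters | None = None,
    config: GibbsConfig | None = None,
    fit_result: FitResult | None = None,
    fallback: str = FALLBACK_LABEL,
    refit: bool = False,
) -> CrossValidationResult:
    """Full protocol: cluster once, then vote and score at every pivot.

    The assignments vector is shared across pivots (transductive
    clustering over all segments; only fold roles change), unless
    ``refit=True`` re-runs the sampler per pivot with the labeled folds
    unchanged — provided as the alternative reading of the protocol.
    """
    folds = corpus.folds()
    if any(f is None for f in folds):
        raise ConfigError("every segment needs a fold index for cross-validation")
    if any(lab is None for lab in corpus.labels()):
        raise ConfigError("every segment needs a label for cross-validation")
    max_fold = max(folds)
    if max_fold >= scheme.F:
        raise ConfigError(f"fold index {max_fold} outside scheme with F={scheme.F}")

    if fit_result is None:
        if config is None:
            raise ConfigError("either fit_result or a GibbsConfig is required")
        fit_result = fit(corpus, hyper=hyper, config=config)

    per_pivot = []
    for pivot in range(scheme.F):
        if refit and config is not None:
            pivot_cfg = GibbsConfig(
                K=config.K,
                iterations=config.iterations,
                seed=config.seed + pivot + 1,
                record_history=config.record_history,
            )
            result = fit(corpus, hyper=hyper, config=pivot_cfg)
        else:
            result = fit_result
        per_pivot.append(
            evaluate_pivot(corpus, result.state.assignments, scheme, pivot, fallback=fallback)
        )
    acc = np.array([r.accuracy for r in per_pivot])
    f1 = np.array([r.macro_f1 for r in per_pivot])
    return CrossValidationResult(
        per_pivot=per_pivot,
        mean_accuracy=float(acc.mean()),
        sd_accuracy=float(acc.std(ddof=1)) if len(acc) > 1 else 0.0,
        mean_macro_f1=float(f1.mean()),
        sd_macro_f1=float(f1.std(ddof=1)) if len(f1) > 1 else 0.0,
        fit_result=fit_result,
    )
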