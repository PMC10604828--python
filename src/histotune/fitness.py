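"""Fitness backends: from a decoded configuration to a scalar score.

A backend turns (configuration, partitioned data, epochs, seed) into
confusion counts plus per-sample scores.  Two backends ship with the
package:

* :class:`SurrogateBackend` — a deterministic analytic landscape peaked at
  a designated optimal configuration.  It ignores the data and lets the
  optimizers be validated exhaustively without any learning machinery.
* :class:`TinyClassifierBackend` — trains a
  :class:`~histotune.estimators.TinyConvNetClassifier` honoring the decoded
  batch size, dropout, loss, weight optimizer and transfer-learn ratio.

``evaluate_solution`` is the optimizer-facing path: decode the vector,
apply the decoded intensity scaling, balance the training part by
augmentation when the decoded gate is on, run the backend, and assemble
the 12-metric report.  The default fitness scalar is test accuracy; the
equal-weight metric sum is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Protocol, runtime_checkable

import numpy as np

from .estimators import TinyConvNetClassifier
from .metrics import (
    ConfusionCounts,
    MetricReport,
    UndefinedMetricError,
    auc_rank,
    compute_metrics,
    cosine_similarity_score,
    micro_confusion,
    weighted_sum,
)
from .preprocessing import SplitDataset, balance_by_augmentation, scale_image
from .search_space import DecodedConfiguration, SearchSpace, decode_solution

__all__ = [
    "BackendResult",
    "FitnessBackend",
    "EvaluationResult",
    "SurrogateBackend",
    "TinyClassifierBackend",
    "evaluate_configuration",
    "evaluate_solution",
]


@dataclass
class BackendResult:
    """Raw evaluation artifacts produced by a backend."""

    counts: ConfusionCounts
    y_true: np.ndarray  # (n,) integer class labels
    probabilities: np.ndarray  # (n, K) rows summing to ~1
    score: float | None = None  # analytic backends report their scalar directly


@runtime_checkable
class FitnessBackend(Protocol):
    def evaluate(
        self, configuration: DecodedConfiguration, data: SplitDataset, epochs: int, seed: int
    ) -> BackendResult: ...


@dataclass
class EvaluationResult:
    """Everything known about one evaluated solution."""

    counts: ConfusionCounts
    report: MetricReport
    fitness: float
    configuration: DecodedConfiguration


# ---------------------------------------------------------------------------
# surrogate backend
# ---------------------------------------------------------------------------

_DEFAULT_OPTIMUM = dict(
    loss_function="kl_divergence",
    batch_size=24,
    dropout=0.3,
    tl_learn_ratio=50,
    parameter_optimizer="sgd_nesterov",
    scaling_technique="standard",
    apply_augmentation=False,
    augmentation=None,
)


class SurrogateBackend:
    """Deterministic analytic fitness landscape over the core hyperparameters.

    The score is ``100 * (1 - mean_d dist_d)`` where ``dist_d`` is the
    normalized distance of the configuration from the designated optimum on
    each of the seven core dimensions (index distance over ``L - 1``
    options for discrete spans, range-normalized absolute difference for
    continuous ones).  The maximum 100 is attained exactly at the optimum
    and the score decreases with every step away from it, so the landscape
    is enumerable and smooth.  Data and epochs are ignored.
    """

    def __init__(self, space: SearchSpace, optimum: DecodedConfiguration | None = None, n_samples: int = 400):
        self.space = space
        self.optimum = DecodedConfiguration(**_DEFAULT_OPTIMUM) if optimum is None else optimum
        self.n_samples = n_samples

    def score(self, config: DecodedConfiguration) -> float:
        dists = []
        for name in (
            "loss_function",
            "batch_size",
            "dropout",
            "tl_learn_ratio",
            "parameter_optimizer",
            "scaling_technique",
            "apply_augmentation",
        ):
            span = self.space.span(name)
            a, b = getattr(config, name), getattr(self.optimum, name)
            if span.is_discrete:
                dists.append(abs(span.options.index(a) - span.options.index(b)) / (span.n_options - 1))
            else:
                lo, hi = span.bounds
                dists.append(abs(a - b) / (hi - lo))
        return 100.0 * (1.0 - float(np.mean(dists)))

    def evaluate(self, configuration, data=None, epochs: int = 0, seed: int = 0) -> BackendResult:
        s = self.score(configuration)
        n = self.n_samples
        correct = int(round(s / 100.0 * n))
        y_true = np.arange(n) % 2
        y_pred = y_true.copy()
        y_pred[correct:] = 1 - y_pred[correct:]  # the tail is misclassified
        probs = np.where(
            (np.arange(n) < correct)[:, None],
            np.where(np.eye(2)[y_true].astype(bool), 0.9, 0.1),
            np.where(np.eye(2)[y_true].astype(bool), 0.35, 0.65),
        )
        counts = micro_confusion(y_true, y_pred, 2)
        return BackendResult(counts=counts, y_true=y_true, probabilities=probs, score=s)


# ---------------------------------------------------------------------------
# trainable backend
# ---------------------------------------------------------------------------

class TinyClassifierBackend:
    """Trainable convolutional backend honoring the decoded hyperparameters.

    Trains on the training part and scores on ``eval_part`` (the test part
    by default; ``"full"`` evaluates on the union of all three parts).
    """

    def __init__(self, n_filters: int = 8, hidden: int = 32, eval_part: str = "test", backbone_seed: int = 0):
        self.n_filters = n_filters
        self.hidden = hidden
        self.eval_part = eval_part
        self.backbone_seed = backbone_seed

    def build_classifier(self, config: DecodedConfiguration, epochs: int, seed: int) -> TinyConvNetClassifier:
        return TinyConvNetClassifier(
            loss=config.loss_function,
            batch_size=config.batch_size,
            dropout=config.dropout,
            learn_ratio=config.tl_learn_ratio,
            optimizer=config.parameter_optimizer,
            epochs=epochs,
            n_filters=self.n_filters,
            hidden=self.hidden,
            backbone_seed=self.backbone_seed,
            random_state=seed,
        )

    @staticmethod
    def _arrays(records) -> tuple[np.ndarray, np.ndarray]:
        X = np.stack([np.asarray(r.pixels, dtype=float) for r in records])
        y = np.array([r.label for r in records])
        return X, y

    def evaluate(self, configuration, data: SplitDataset, epochs: int, seed: int) -> BackendResult:
        clf = self.build_classifier(configuration, epochs, seed)
        X_train, y_train = self._arrays(data.train)
        clf.fit(X_train, y_train)
        if self.eval_part == "full":
            eval_records = data.train + data.validation + data.test
        else:
            eval_records = getattr(data, self.eval_part)
        X_eval, y_eval = self._arrays(eval_records)
        probs = clf.predict_proba(X_eval)
        pred = clf.classes_[np.argmax(probs, axis=1)]
        classes = list(clf.classes_)
        y_idx = np.array([classes.index(v) for v in y_eval])
        p_idx = np.array([classes.index(v) for v in pred])
        counts = micro_confusion(y_idx, p_idx, len(classes))
        return BackendResult(counts=counts, y_true=y_idx, probabilities=probs)


# ---------------------------------------------------------------------------
# evaluation pathway
# ---------------------------------------------------------------------------

def _scale_split(data: SplitDataset, method: str) -> SplitDataset:
    scale = lambda part: [replace(r, pixels=scale_image(np.asarray(r.pixels, dtype=float), method)) for r in part]
    return SplitDataset(train=scale(data.train), validation=scale(data.validation), test=scale(data.test))


def evaluate_configuration(
    config: DecodedConfiguration,
    backend: FitnessBackend,
    data: SplitDataset,
    epochs: int = 5,
    seed: int = 0,
    fitness_metric: str = "accuracy",
) -> EvaluationResult:
    """Run one decoded configuration through the full evaluation pathway."""
    if isinstance(backend, SurrogateBackend):
        # analytic landscape: no data transformation is observable
        res = backend.evaluate(config, data, epochs, seed)
    else:
        working = _scale_split(data, config.scaling_technique)
        if config.apply_augmentation:
            working = SplitDataset(
                train=balance_by_augmentation(working.train, config.augmentation, seed=seed),
                validation=working.validation,
                test=working.test,
            )
        res = backend.evaluate(config, working, epochs, seed)

    report = compute_metrics(res.counts)
    y = np.asarray(res.y_true)
    k = res.probabilities.shape[1]
    auc = cos = None
    if k == 2 and len(np.unique(y)) == 2:
        auc = auc_rank(y, res.probabilities[:, 1])
    try:
        cos = cosine_similarity_score(np.eye(k)[y], res.probabilities)
    except UndefinedMetricError:
        cos = None
    report = report.with_scores(auc=auc, cosine_similarity=cos)

    if res.score is not None:
        fitness = float(res.score)
    elif fitness_metric == "accuracy":
        fitness = float(report.accuracy)
    elif fitness_metric in ("weighted_sum", "ws"):
        fitness = weighted_sum(report)
    else:
        raise ValueError(f"unknown fitness metric {fitness_metric!r}")
    return EvaluationResult(counts=res.counts, report=report, fitness=fitness, configuration=config)


def evaluate_solution(
    vector: np.ndarray,
    space: SearchSpace,
    backend: FitnessBackend,
    data: SplitDataset,
    epochs: int = 5,
    seed: int = 0,
    fitness_metric: str = "accuracy",
) -> EvaluationResult:
    """Decode a normalized solution vector and evaluate it."""
    config = decode_solution(vector, space)
    return evaluate_configuration(
        config, backend, data, epochs=epochs, seed=seed, fitness_metric=fitness_metric
    )
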