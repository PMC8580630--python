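"""Wrapper feature selection driven by the dTEO minimiser.

A candidate solution is a point in the unit hypercube over the feature
axes; components above 0.5 mark selected features.  Each candidate is
scored by the cross-validated Matthews correlation coefficient (MCC) of an
extreme learning machine trained on the masked features, and dTEO
minimises ``1 - mean MCC``.  MCC is a correlation in [-1, 1] between
predicted and true labels, so its maximum — not its minimum — identifies
the best classifier; minimising the raw coefficient would reward inverted
classifiers, which is why the complement is the objective.

Empty masks receive an infinite cost, so the returned mask always contains
at least one feature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import elm
from .exceptions import ConfigError, DataError
from .optimizer import OptimizerConfig, minimize

__all__ = [
    "ConfusionCounts",
    "FeatureMask",
    "SelectionConfig",
    "fitness",
    "confusion_from_labels",
    "cv_fitness",
    "select",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN of a binary classification outcome."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise DataError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class FeatureMask:
    """Boolean selection over feature columns plus the achieved fitness."""

    selected: np.ndarray
    fitness: float
    names: tuple[str, ...] | None = None


@dataclass
class SelectionConfig:
    """Budget and inner-classifier settings for the wrapper search."""

    population_size: int = 20
    iterations: int = 40
    k_folds: int = 5
    hidden: int = 30
    threshold: float = 0.5
    inner_seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ConfigError("k_folds must be >= 2")
        if not 0.0 < self.threshold < 1.0:
            raise ConfigError("threshold must lie in (0, 1)")


def fitness(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient of a confusion table.

    ``(tp*tn - fp*fn) / sqrt((tn+fp)(tp+fp)(tp+fn)(tn+fn))``; a table with
    any zero marginal has no defined correlation and scores 0 by
    convention.
    """
    denom = (
        (c.tn + c.fp) * (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fn)
    )
    if denom <= 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def confusion_from_labels(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Confusion counts with class 1 as the positive class."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mu) / sd, (test - mu) / sd


def cv_fitness(
    X: np.ndarray, y: np.ndarray, config: SelectionConfig
) -> float:
    """Mean per-fold MCC of an ELM over stratified k-fold splits.

    Features are z-scored with train-fold statistics; the inner ELM uses a
    fixed seed per fold so that different feature masks are compared on
    identical random hidden layers.
    """
    skf = StratifiedKFold(
        n_splits=config.k_folds, shuffle=True, random_state=config.inner_seed
    )
    scores = []
    onehot = np.eye(2)[y]
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        xtr, xte = _standardize(X[tr], X[te])
        model = elm.fit(
            xtr,
            onehot[tr],
            elm.TrainConfig(hidden=config.hidden, seed=config.inner_seed + fold),
        )
        pred, _ = elm.predict(model, xte)
        scores.append(fitness(confusion_from_labels(y[te], pred)))
    return float(np.mean(scores))


def select(
    features: np.ndarray,
    labels: np.ndarray,
    config: SelectionConfig | None = None,
    rng: np.random.Generator | None = None,
    names: tuple[str, ...] | None = None,
) -> FeatureMask:
    """dTEO wrapper search for the feature subset maximising the CV MCC."""
    if config is None:
        config = SelectionConfig()
    if rng is None:
        rng = np.random.default_rng()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise DataError("selection requires exactly two classes")
    if counts.min() < 2:
        raise DataError("each class needs at least two cases")
    y = (y == classes.max()).astype(int)
    n_feat = X.shape[1]

    def objective(v: np.ndarray) -> float:
        mask = v > config.threshold
        if not mask.any():
            return math.inf
        return 1.0 - cv_fitness(X[:, mask], y, config)

    opt_cfg = OptimizerConfig(
        bounds_low=np.zeros(n_feat),
        bounds_high=np.ones(n_feat),
        population_size=config.population_size,
        max_iterations=config.iterations,
        variant="dteo",
    )
    result = minimize(objective, opt_cfg, rng)
    mask = result.best_vector > config.threshold
    if not mask.any():
        # pathological: no finite candidate was ever evaluated
        mask[int(np.argmax(result.best_vector))] = True
    return FeatureMask(
        selected=mask, fitness=1.0 - float(result.best_cost), names=names
    )
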