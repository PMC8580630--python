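"""Confusion-matrix metrics and the repeated hold-out protocol.

Five standard screening metrics are computed from TP/TN/FP/FN with
melanoma as the positive class:

* accuracy     = (TP + TN) / total
* sensitivity  = TP / (TP + FN)
* specificity  = TN / (TN + FP)
* PPV          = TP / (TP + FP)
* NPV          = TN / (TN + FN)

The experiment protocol repeats, 15 times by default: a stratified 80/20
train/test split, wrapper feature selection on the training split, an
activation-optimised ELM trained on the selected features, and metric
evaluation on the held-out split.  Reported metrics are means over
repeats; the pooled confusion counts are kept alongside.  Selection is
refit inside every repeat so no information leaks from test splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import elm
from .exceptions import DataError
from .selection import (
    ConfusionCounts,
    SelectionConfig,
    _standardize,
    confusion_from_labels,
    select,
)

__all__ = ["MetricsReport", "ExperimentConfig", "metrics", "run_experiment"]


@dataclass
class MetricsReport:
    """The five screening metrics plus the counts they derive from."""

    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    counts: ConfusionCounts
    repeats: int = 1
    per_repeat: pd.DataFrame | None = None


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined: zero denominator")
        return float("nan")
    return num / den


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Compute the five metrics from one confusion table."""
    if c.total == 0:
        raise DataError("no evaluated cases")
    report = MetricsReport(
        accuracy=(c.tp + c.tn) / c.total,
        sensitivity=_ratio(c.tp, c.tp + c.fn, "sensitivity"),
        specificity=_ratio(c.tn, c.tn + c.fp, "specificity"),
        ppv=_ratio(c.tp, c.tp + c.fp, "PPV"),
        npv=_ratio(c.tn, c.tn + c.fn, "NPV"),
        counts=c,
    )
    # prevalence-weighted identity: accuracy = (sens*P + spec*N) / (P + N)
    pos, neg = c.tp + c.fn, c.tn + c.fp
    if pos > 0 and neg > 0:
        assert abs(
            report.accuracy
            - (report.sensitivity * pos + report.specificity * neg) / (pos + neg)
        ) < 1e-12
    return report


@dataclass
class ExperimentConfig:
    """Protocol settings: repeats, split fraction and stage budgets."""

    repeats: int = 15
    test_fraction: float = 0.2
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    train: elm.TrainConfig = field(default_factory=elm.TrainConfig)


def run_experiment(
    features: np.ndarray | pd.DataFrame,
    labels: np.ndarray,
    config: ExperimentConfig | None = None,
    rng: np.random.Generator | None = None,
) -> MetricsReport:
    """Repeated stratified hold-out evaluation of the full classifier chain.

    Each repeat draws its own 80/20 stratified split, reruns feature
    selection on the training split, trains the activation-optimised ELM
    on the selected features and scores the held-out split.  Metric means
    are averaged over repeats; counts are pooled.
    """
    if config is None:
        config = ExperimentConfig()
    if rng is None:
        rng = np.random.default_rng()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    classes = np.unique(y)
    if classes.size != 2:
        raise DataError("evaluation requires exactly two classes")
    y = (y == classes.max()).astype(int)

    rows = []
    pooled = dict(tp=0, tn=0, fp=0, fn=0)
    for rep in range(config.repeats):
        split_seed = int(rng.integers(2**31 - 1))
        xtr, xte, ytr, yte = train_test_split(
            X,
            y,
            test_size=config.test_fraction,
            stratify=y,
            random_state=split_seed,
        )
        mask = select(xtr, ytr, config.selection, rng).selected
        xtr_s, xte_s = _standardize(xtr[:, mask], xte[:, mask])
        model = elm.optimize_activation(xtr_s, np.eye(2)[ytr], config.train, rng)
        pred, _ = elm.predict(model, xte_s)
        c = confusion_from_labels(yte, pred)
        rep_metrics = metrics(c)
        pooled["tp"] += c.tp
        pooled["tn"] += c.tn
        pooled["fp"] += c.fp
        pooled["fn"] += c.fn
        rows.append(
            {
                "repeat": rep,
                "accuracy": rep_metrics.accuracy,
                "sensitivity": rep_metrics.sensitivity,
                "specificity": rep_metrics.specificity,
                "ppv": rep_metrics.ppv,
                "npv": rep_metrics.npv,
                "n_selected": int(mask.sum()),
            }
        )
    table = pd.DataFrame(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = table[["accuracy", "sensitivity", "specificity", "ppv", "npv"]].mean()
    return MetricsReport(
        accuracy=float(means["accuracy"]),
        sensitivity=float(means["sensitivity"]),
        specificity=float(means["specificity"]),
        ppv=float(means["ppv"]),
        npv=float(means["npv"]),
        counts=ConfusionCounts(**pooled),
        repeats=config.repeats,
        per_repeat=table,
    )
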