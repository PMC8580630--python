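"""Extreme Learning Machine with metaheuristically tuned activations.

A single-hidden-layer feed-forward network trained in closed form: input
weights ``w_m`` and biases ``b_m`` are drawn once from a uniform(-1, 1)
distribution and never trained; the hidden activations
``H[n, m] = sigmoid(as * (w_m . x_n + b_m) + bs_m)`` are computed for all
training samples, and the output weights solve the least-squares problem
``beta = H^+ T`` through the Moore–Penrose pseudoinverse.

Each hidden neuron carries its own sigmoid shape parameter ``bs_m`` (the
global gain ``as`` is fixed at 1, since the two parameters shape the
activation almost interchangeably).  ``optimize_activation`` searches the
``bs`` vector with the dTEO minimiser, refitting ``beta`` for every
candidate and scoring the mean squared error between network outputs and
one-hot targets; the all-ones ``bs`` baseline of a plain fit is inside the
search box, and the returned model is never worse than that baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .exceptions import ConfigError, DataError
from .optimizer import OptimizerConfig, minimize

__all__ = [
    "ELMModel",
    "TrainConfig",
    "sigmoid",
    "hidden_matrix",
    "fit",
    "predict",
    "sse_objective",
    "optimize_activation",
    "model_to_json",
    "model_from_json",
]


def sigmoid(s, as_value: float = 1.0, bs_value: float = 0.0):
    """Overflow-safe logistic activation ``1 / (1 + exp(-(as*s + bs)))``."""
    return expit(as_value * np.asarray(s, dtype=float) + bs_value)


@dataclass
class ELMModel:
    """Random-projection hidden layer plus least-squares output weights."""

    input_weights: np.ndarray  # M x D
    biases: np.ndarray  # M
    slopes: np.ndarray  # M, per-neuron sigmoid shape parameter bs
    output_weights: np.ndarray | None = None  # M x K
    as_value: float = 1.0

    @property
    def fitted(self) -> bool:
        return self.output_weights is not None


@dataclass
class TrainConfig:
    """Hidden-layer size and the activation-search budget.

    ``opt_iterations`` is the dTEO budget for the ``bs`` search; the
    network itself trains in one shot.
    """

    hidden: int = 50
    as_value: float = 1.0
    bs_low: float = -5.0
    bs_high: float = 5.0
    opt_population: int = 20
    opt_iterations: int = 700
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.hidden < 1:
            raise ConfigError("hidden must be >= 1")
        if self.bs_low >= self.bs_high:
            raise ConfigError("bs_low must be < bs_high")


def hidden_matrix(X: np.ndarray, model: ELMModel) -> np.ndarray:
    """Hidden activations ``H[n, m] = sigmoid(w_m . x_n + b_m; bs_m)``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    s = X @ model.input_weights.T + model.biases
    return expit(model.as_value * s + model.slopes)


def _solve_beta(H: np.ndarray, T: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(H, T, rcond=None)
    return beta


def fit(
    X: np.ndarray,
    targets: np.ndarray,
    config: TrainConfig | None = None,
    rng: np.random.Generator | None = None,
) -> ELMModel:
    """One-shot ELM training: random hidden layer, pseudoinverse readout.

    ``targets`` is an N x K one-hot (or real-valued) matrix.  The sigmoid
    shape parameters start at 1 for every neuron; use
    :func:`optimize_activation` to tune them.
    """
    if config is None:
        config = TrainConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T = np.atleast_2d(np.asarray(targets, dtype=float))
    if not np.all(np.isfinite(X)):
        raise DataError("non-finite feature values")
    if X.shape[0] != T.shape[0]:
        raise DataError("X and targets row counts differ")
    m, d = config.hidden, X.shape[1]
    model = ELMModel(
        input_weights=rng.uniform(-1.0, 1.0, (m, d)),
        biases=rng.uniform(-1.0, 1.0, m),
        slopes=np.ones(m),
        as_value=config.as_value,
    )
    model.output_weights = _solve_beta(hidden_matrix(X, model), T)
    return model


def predict(model: ELMModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class labels (argmax over output columns) and raw scores."""
    if not model.fitted:
        raise DataError("model has no output weights; fit it first")
    scores = hidden_matrix(X, model) @ model.output_weights
    return np.argmax(scores, axis=1), scores


def sse_objective(model: ELMModel, X: np.ndarray, T: np.ndarray) -> float:
    """Mean (over samples) summed squared error between outputs and targets."""
    _, scores = predict(model, X)
    return float(np.sum((T - scores) ** 2) / X.shape[0])


def optimize_activation(
    X: np.ndarray,
    targets: np.ndarray,
    config: TrainConfig | None = None,
    rng: np.random.Generator | None = None,
) -> ELMModel:
    """Tune the per-neuron sigmoid parameters with dTEO.

    Input weights and biases are initialised once and held fixed; dTEO
    searches the M-dimensional ``bs`` box, refitting the output weights
    for every candidate and minimising the mean squared one-hot error.
    The plain all-ones-``bs`` fit is evaluated as a baseline and returned
    if the search does not improve on it.
    """
    if config is None:
        config = TrainConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T = np.atleast_2d(np.asarray(targets, dtype=float))
    baseline = fit(X, T, config, rng)
    base_err = sse_objective(baseline, X, T)
    m = config.hidden

    def objective(bs: np.ndarray) -> float:
        trial = ELMModel(
            input_weights=baseline.input_weights,
            biases=baseline.biases,
            slopes=bs,
            as_value=config.as_value,
        )
        trial.output_weights = _solve_beta(hidden_matrix(X, trial), T)
        return sse_objective(trial, X, T)

    opt_cfg = OptimizerConfig(
        bounds_low=np.full(m, config.bs_low),
        bounds_high=np.full(m, config.bs_high),
        population_size=config.opt_population,
        max_iterations=config.opt_iterations,
        variant="dteo",
    )
    result = minimize(objective, opt_cfg, rng)
    if result.best_cost >= base_err:
        return baseline
    best = ELMModel(
        input_weights=baseline.input_weights,
        biases=baseline.biases,
        slopes=result.best_vector,
        as_value=config.as_value,
    )
    best.output_weights = _solve_beta(hidden_matrix(X, best), T)
    return best


def model_to_json(model: ELMModel) -> str:
    """Serialise a model as JSON (shapes plus flat arrays)."""
    import json

    payload = {
        "shape": list(model.input_weights.shape),
        "input_weights": model.input_weights.ravel().tolist(),
        "biases": model.biases.tolist(),
        "slopes": model.slopes.tolist(),
        "as_value": model.as_value,
        "output_weights": None
        if model.output_weights is None
        else {
            "shape": list(model.output_weights.shape),
            "data": model.output_weights.ravel().tolist(),
        },
    }
    return json.dumps(payload)


def model_from_json(text: str) -> ELMModel:
    import json

    payload = json.loads(text)
    ow = payload["output_weights"]
    return ELMModel(
        input_weights=np.array(payload["input_weights"]).reshape(payload["shape"]),
        biases=np.array(payload["biases"]),
        slopes=np.array(payload["slopes"]),
        as_value=float(payload["as_value"]),
        output_weights=None if ow is None else np.array(ow["data"]).reshape(ow["shape"]),
    )
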