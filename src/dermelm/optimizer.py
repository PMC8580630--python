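"""Thermal Exchange Optimization (TEO) and its developed variant (dTEO).

TEO is a population metaheuristic modelled on Newton's law of cooling: each
candidate solution is a vector of "temperatures".  The population is split
into a better half (environment objects) and a worse half (cooling objects);
every cooling object relaxes exponentially toward its paired environment
object, with a per-candidate cooling coefficient given by the ratio of its
cost to the worst cost in the population.  An elitist *thermal memory*
archives the best vectors ever seen and re-injects them in place of the
worst population members each iteration.

The developed variant (dTEO) makes two changes aimed at a better
exploration/exploitation balance:

* the uniform random stream that scales the environment perturbation,
  the dimension-reset draw and the initial population is replaced by a
  sinusoidal chaotic map ``f -> alpha * f**2 * sin(pi * f)``;
* each updated candidate receives a multiplicative Gaussian mutation
  ``x -> x * (1 + gamma * g)`` whose amplitude ``gamma`` decays with the
  iteration fraction, so late iterations mutate only gently.

Both variants minimise a black-box objective over a box-bounded continuous
domain.  All randomness flows from a single :class:`numpy.random.Generator`
(plus the deterministic chaotic stream), so runs are reproducible from a
seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .exceptions import ConfigError

__all__ = [
    "OptimizerConfig",
    "ThermalState",
    "OptimizationResult",
    "ChaoticStream",
    "chaos_next",
    "initialize_population",
    "cost_ratio",
    "step",
    "gaussian_mutate",
    "minimize",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12

Objective = Callable[[np.ndarray], float]


def chaos_next(f: float, alpha: float) -> float:
    """One iterate of the sinusoidal chaotic map ``alpha * f**2 * sin(pi f)``.

    Values escaping the open unit interval are reflected back to its
    interior (``>= 1`` maps to ``1 - eps``, ``<= 0`` to ``eps``) so that the
    stream can always be iterated again.

    Parameters
    ----------
    f
        Current state, strictly inside ``(0, 1)``.
    alpha
        Map gain in ``(0, 4]``; ``2.3`` keeps the map in its chaotic regime
        while staying inside the unit interval for almost every state.
    """
    if not 0.0 < f < 1.0:
        raise ConfigError(f"chaotic state must lie in (0, 1), got {f!r}")
    v = alpha * f * f * math.sin(math.pi * f)
    if v >= 1.0:
        v = 1.0 - _EPS
    elif v <= 0.0:
        v = _EPS
    return v


class ChaoticStream:
    """Deterministic stream of pseudo-random numbers from the chaotic map.

    Used by dTEO wherever TEO would draw from the uniform stream (initial
    population, environment perturbation, dimension reset).
    """

    def __init__(self, f0: float, alpha: float) -> None:
        if not 0.0 < f0 < 1.0:
            raise ConfigError(f"chaos_f0 must lie in (0, 1), got {f0!r}")
        self.state = float(f0)
        self.alpha = float(alpha)

    def draw(self) -> float:
        self.state = chaos_next(self.state, self.alpha)
        return self.state

    def draw_array(self, shape) -> np.ndarray:
        n = int(np.prod(shape))
        out = np.empty(n)
        for i in range(n):
            out[i] = self.draw()
        return out.reshape(shape)


@dataclass
class OptimizerConfig:
    """Run parameters for TEO/dTEO.

    ``bounds_low``/``bounds_high`` define the box domain (the minimum and
    maximum admissible temperatures).  ``pr`` is the per-candidate
    probability that one uniformly chosen dimension is reset each
    iteration.  ``m1``/``m2`` (each 0 or 1) control how strongly the
    environment temperature is perturbed: with ``m1=0, m2=1`` the
    perturbation amplitude decays linearly with the iteration fraction.
    ``reset_style`` selects whether the dimension-reset span is damped by
    ``exp(-gamma * t)`` (``"printed"``) or not (``"plain"``).
    """

    bounds_low: Sequence[float]
    bounds_high: Sequence[float]
    population_size: int = 120
    max_iterations: int = 100
    pr: float = 0.3
    m1: int = 0
    m2: int = 1
    memory_size: int | None = None
    chaos_alpha: float = 2.3
    chaos_f0: float | None = None
    variant: str = "dteo"
    seed: int | None = None
    reset_style: str = "printed"
    mutate_whole_population: bool = False
    swap_roles: bool = False

    def __post_init__(self) -> None:
        self.bounds_low = np.asarray(self.bounds_low, dtype=float)
        self.bounds_high = np.asarray(self.bounds_high, dtype=float)
        if self.bounds_low.shape != self.bounds_high.shape or self.bounds_low.ndim != 1:
            raise ConfigError("bounds_low and bounds_high must be 1-D and equally shaped")
        if np.any(self.bounds_low > self.bounds_high):
            raise ConfigError("bounds_low must not exceed bounds_high")
        if self.population_size < 2 or self.population_size % 2:
            raise ConfigError("population_size must be an even integer >= 2")
        if self.max_iterations < 1:
            raise ConfigError("max_iterations must be positive")
        if not 0.0 <= self.pr <= 1.0:
            raise ConfigError("pr must lie in [0, 1]")
        if self.m1 not in (0, 1) or self.m2 not in (0, 1):
            raise ConfigError("m1 and m2 must each be 0 or 1")
        if not 0.0 < self.chaos_alpha <= 4.0:
            raise ConfigError("chaos_alpha must lie in (0, 4]")
        if self.chaos_f0 is not None and not 0.0 < self.chaos_f0 < 1.0:
            raise ConfigError("chaos_f0 must lie in (0, 1)")
        if self.variant not in ("teo", "dteo"):
            raise ConfigError(f"unknown variant {self.variant!r}")
        if self.reset_style not in ("printed", "plain"):
            raise ConfigError(f"unknown reset_style {self.reset_style!r}")
        if self.memory_size is None:
            self.memory_size = max(2, self.population_size // 10)
        if not 0 <= self.memory_size <= self.population_size:
            raise ConfigError("memory_size must lie in [0, population_size]")

    @property
    def dim(self) -> int:
        return self.bounds_low.shape[0]


@dataclass
class ThermalState:
    """Population snapshot: candidate temperatures, costs and the memory."""

    temperatures: np.ndarray
    costs: np.ndarray
    memory: list[tuple[np.ndarray, float]] = field(default_factory=list)
    iteration: int = 0
    chaos_state: float = 0.7

    @property
    def evaluated(self) -> bool:
        return bool(np.all(np.isfinite(self.costs) | np.isposinf(self.costs)))


@dataclass
class OptimizationResult:
    """Best-ever solution plus the per-iteration best-cost trace."""

    best_vector: np.ndarray
    best_cost: float
    history: np.ndarray
    evaluations: int


def initialize_population(
    config: OptimizerConfig, rng: np.random.Generator
) -> ThermalState:
    """Draw the initial temperatures uniformly inside the box.

    ``T_i = T_min + u * (T_max - T_min)`` per dimension; for the dTEO
    variant ``u`` comes from the chaotic stream instead of the uniform one.
    Costs are left as a NaN sentinel until first evaluation.
    """
    n, d = config.population_size, config.dim
    f0 = config.chaos_f0
    if f0 is None:
        # The sinusoidal map has an absorbing fixed point at 0: orbits
        # started below ~0.45 (or above ~0.93) fall into its basin and the
        # stream stops being chaotic.  Auto-drawn seeds therefore come from
        # the chaotic attractor, whose support for alpha=2.3 is ~[0.49, 0.92].
        f0 = float(rng.uniform(0.5, 0.9))
    stream = ChaoticStream(f0, config.chaos_alpha)
    if config.variant == "dteo":
        u = stream.draw_array((n, d))
    else:
        u = rng.random((n, d))
    temps = config.bounds_low + u * (config.bounds_high - config.bounds_low)
    return ThermalState(
        temperatures=temps,
        costs=np.full(n, np.nan),
        memory=[],
        iteration=0,
        chaos_state=stream.state,
    )


def cost_ratio(cost_i: float, cost_worst: float) -> float:
    """Cooling coefficient: cost of the object over the worst cost.

    Costs must already be shifted non-negative.  A zero worst cost means an
    all-equal population, for which the ratio is 1 by convention.
    """
    if cost_worst == 0.0:
        return 1.0
    return float(cost_i) / float(cost_worst)


def gaussian_mutate(
    vector: np.ndarray, decay: float, rng: np.random.Generator
) -> np.ndarray:
    """Multiplicative Gaussian mutation ``x -> x * (1 + decay * g)``."""
    g = rng.standard_normal(np.shape(vector))
    return np.asarray(vector) * (1.0 + decay * g)


def _evaluate(objective: Objective, vectors: np.ndarray) -> np.ndarray:
    """Evaluate the objective row-wise; non-finite values become +inf."""
    costs = np.empty(len(vectors))
    for i, v in enumerate(vectors):
        c = float(objective(v))
        if not math.isfinite(c):
            logger.warning("objective returned non-finite cost %r; using +inf", c)
            c = math.inf
        costs[i] = c
    return costs


def _cooling_coefficients(costs: np.ndarray) -> np.ndarray:
    """Per-candidate cost ratios after shifting costs non-negative.

    Infinite costs (failed evaluations) get the worst possible ratio 1.
    """
    finite = np.isfinite(costs)
    if not finite.any():
        return np.ones_like(costs)
    shifted = costs - costs[finite].min() + _EPS
    worst = shifted[finite].max()
    ratios = np.ones_like(costs)
    ratios[finite] = np.array([cost_ratio(c, worst) for c in shifted[finite]])
    return np.clip(ratios, 0.0, 1.0)


def _update_memory(
    memory: list[tuple[np.ndarray, float]],
    temps: np.ndarray,
    costs: np.ndarray,
    memory_size: int,
) -> list[tuple[np.ndarray, float]]:
    pool = list(memory) + [(temps[i].copy(), float(costs[i])) for i in range(len(costs))]
    pool.sort(key=lambda vc: vc[1])
    return pool[:memory_size]


def step(
    state: ThermalState,
    objective: Objective,
    config: OptimizerConfig,
    rng: np.random.Generator,
) -> ThermalState:
    """Advance the population by one cooling iteration.

    The population is sorted ascending by cost; the better half acts as the
    environment for the worse (cooling) half, pairing the i-th cooling
    object with the i-th environment object.  Each cooling object moves to

        ``env' + (T_old - env') * exp(-gamma * t)``

    where ``env' = (1 - (m1 + m2 * (1 - t)) * r) * T_env``, ``t`` is the
    iteration fraction and ``gamma`` the object's cost ratio.  With
    probability ``pr`` one random dimension is re-drawn from the box.  dTEO
    additionally applies the decaying Gaussian mutation.  Updated
    candidates are clipped to the box and re-evaluated, and the thermal
    memory replaces the worst ``memory_size`` candidates.
    """
    if np.isnan(state.costs).any():
        raise ConfigError("step() requires an evaluated population")

    low, high = config.bounds_low, config.bounds_high
    n = config.population_size
    half = n // 2
    iteration = state.iteration + 1
    t = iteration / config.max_iterations

    order = np.argsort(state.costs, kind="stable")
    temps = state.temperatures[order].copy()
    costs = state.costs[order].copy()

    gammas = _cooling_coefficients(costs)
    stream = ChaoticStream(state.chaos_state, config.chaos_alpha)
    chaotic = config.variant == "dteo"

    def draw_r() -> float:
        return stream.draw() if chaotic else float(rng.random())

    new_cool = np.empty_like(temps[half:])
    for k in range(half):
        i = half + k  # cooling object index in the sorted population
        gamma = gammas[i]
        env = temps[k]
        r = draw_r()
        env_new = (1.0 - (config.m1 + config.m2 * (1.0 - t)) * r) * env
        cand = env_new + (temps[i] - env_new) * math.exp(-gamma * t)
        if config.pr > 0.0 and rng.random() < config.pr:
            d = int(rng.integers(config.dim))
            span = high[d] - low[d]
            damp = math.exp(-gamma * t) if config.reset_style == "printed" else 1.0
            cand[d] = low[d] + draw_r() * span * damp
        if chaotic and not config.mutate_whole_population:
            decay = float(rng.random()) * (1.0 - t)
            cand = gaussian_mutate(cand, decay, rng)
        new_cool[k] = cand

    temps[half:] = new_cool
    if chaotic and config.mutate_whole_population:
        for i in range(n):
            decay = float(rng.random()) * (1.0 - t)
            temps[i] = gaussian_mutate(temps[i], decay, rng)
        np.clip(temps, low, high, out=temps)
        costs = _evaluate(objective, temps)
    else:
        np.clip(temps[half:], low, high, out=temps[half:])
        costs[half:] = _evaluate(objective, temps[half:])

    memory = _update_memory(state.memory, temps, costs, config.memory_size)
    if memory:
        worst = np.argsort(costs, kind="stable")[::-1][: len(memory)]
        for idx, (vec, cost) in zip(worst, memory):
            temps[idx] = vec.copy()
            costs[idx] = cost

    return ThermalState(
        temperatures=temps,
        costs=costs,
        memory=memory,
        iteration=iteration,
        chaos_state=stream.state,
    )


def minimize(
    objective: Objective,
    config: OptimizerConfig,
    rng: np.random.Generator | None = None,
) -> OptimizationResult:
    """Run the full TEO/dTEO loop and return the best-ever solution.

    The history records the best-ever cost after initialization and after
    each iteration, so it is non-increasing by construction of the thermal
    memory.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)

    evaluations = 0

    def counted(x: np.ndarray) -> float:
        nonlocal evaluations
        evaluations += 1
        return objective(x)

    state = initialize_population(config, rng)
    state.costs = _evaluate(counted, state.temperatures)
    state.memory = _update_memory(
        state.memory, state.temperatures, state.costs, config.memory_size
    )

    i_best = int(np.argmin(state.costs))
    best_vec = state.temperatures[i_best].copy()
    best_cost = float(state.costs[i_best])
    history = [best_cost]
    for _ in range(config.max_iterations):
        state = step(state, counted, config, rng)
        i = int(np.argmin(state.costs))
        if state.costs[i] < best_cost:
            best_cost = float(state.costs[i])
            best_vec = state.temperatures[i].copy()
        history.append(best_cost)

    best_vec = np.clip(best_vec, config.bounds_low, config.bounds_high)
    return OptimizationResult(
        best_vector=best_vec,
        best_cost=float(best_cost),
        history=np.asarray(history),
        evaluations=evaluations,
    )
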