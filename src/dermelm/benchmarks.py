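"""Benchmark test functions and the min/std comparison protocol.

Eight classical box-bounded minimisation problems (sphere, Rosenbrock,
Rastrigin, Griewank, a noisy quartic, two bivariate multimodal surfaces and
a shifted-cosine sum) used to validate the optimizer.  The comparison
protocol runs each algorithm ``reps`` times with independent seeds and
reports the minimum and standard deviation of the per-run best costs.

Unbounded formulations are given the standard finite literature boxes
(sphere ±100, Rosenbrock ±30, Rastrigin ±5.12, quartic ±1.28,
Griewank ±600); those are documented defaults, not part of the functions
themselves.

Two functions need caveats.  F3, ``sum(x_n - 10 cos(10 x_n))``, is kept in
this printed shifted-cosine form although its analytic minimum on the box
is well below the commonly quoted 0; it is therefore excluded from exact
minimum checks.  F8 is a Schaffer-like ratio whose quoted minimum does not
match the canonical Schaffer function; it is likewise implemented as
printed and excluded from exact checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize as sp_optimize

from .exceptions import ConfigError
from .optimizer import OptimizerConfig, minimize

__all__ = [
    "BenchmarkFunction",
    "BenchmarkReport",
    "make_suite",
    "get_function",
    "grid_refine_min",
    "run_protocol",
]


@dataclass(frozen=True)
class BenchmarkFunction:
    """A named test function with its box domain and known minimum value."""

    name: str
    dim: int
    bounds_low: np.ndarray
    bounds_high: np.ndarray
    evaluate: Callable[[np.ndarray], float]
    known_min: float | None
    noisy: bool = False


def _f1_sphere(x: np.ndarray) -> float:
    return float(np.sum(x * x))


def _f2_rosenbrock(x: np.ndarray) -> float:
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))


def _f3_shifted_cos(x: np.ndarray) -> float:
    return float(np.sum(x - 10.0 * np.cos(10.0 * x)))


def _f4_bivariate_sin(x: np.ndarray) -> float:
    return float(x[0] * math.sin(4.0 * x[0]) + 1.1 * x[1] * math.sin(2.0 * x[1]))


def _f6_rastrigin(x: np.ndarray) -> float:
    n = x.shape[0]
    return float(10.0 * n + np.sum(x * x - 10.0 * np.cos(2.0 * math.pi * x)))


def _f7_griewank(x: np.ndarray) -> float:
    n = np.arange(1, x.shape[0] + 1, dtype=float)
    return float(1.0 + np.sum(x * x) / 4000.0 - np.prod(np.cos(x / np.sqrt(n))))


def _f8_schaffer_like(x: np.ndarray) -> float:
    r2 = float(x[0] ** 2 + x[1] ** 2)
    return 0.5 + (math.sin(math.sqrt(r2)) ** 2 - 0.5) / (1.0 + 0.1 * r2) ** 2


def make_suite(
    dim_multivariate: int = 30, rng: np.random.Generator | None = None
) -> list[BenchmarkFunction]:
    """Build F1..F8.

    ``dim_multivariate`` sets the dimension of the N-dimensional functions
    (F4 and F8 are intrinsically 2-D).  ``rng`` feeds the additive
    standard-normal noise of the quartic F5; a fresh default generator is
    used when omitted, so F5 is stochastic by design.
    """
    if dim_multivariate < 2:
        raise ConfigError("dim_multivariate must be >= 2")
    noise_rng = rng if rng is not None else np.random.default_rng()
    d = dim_multivariate

    def _f5_noisy_quartic(x: np.ndarray) -> float:
        n = np.arange(1, x.shape[0] + 1, dtype=float)
        return float(np.sum(n * x**4) + noise_rng.standard_normal())

    def box(lo: float, hi: float, dim: int) -> tuple[np.ndarray, np.ndarray]:
        return np.full(dim, lo), np.full(dim, hi)

    specs = [
        ("F1", d, box(-100.0, 100.0, d), _f1_sphere, 0.0, False),
        ("F2", d, box(-30.0, 30.0, d), _f2_rosenbrock, 0.0, False),
        ("F3", d, box(-5.12, 5.12, d), _f3_shifted_cos, None, False),
        ("F4", 2, box(0.0, 10.0, 2), _f4_bivariate_sin, -18.5547, False),
        ("F5", d, box(-1.28, 1.28, d), _f5_noisy_quartic, None, True),
        ("F6", d, box(-5.12, 5.12, d), _f6_rastrigin, 0.0, False),
        ("F7", d, box(-600.0, 600.0, d), _f7_griewank, 0.0, False),
        ("F8", 2, box(-100.0, 100.0, 2), _f8_schaffer_like, None, False),
    ]
    return [
        BenchmarkFunction(name, dim, lo, hi, fn, kmin, noisy)
        for name, dim, (lo, hi), fn, kmin, noisy in specs
    ]


def get_function(name: str, dim_multivariate: int = 30) -> BenchmarkFunction:
    """Look a suite function up by name (case-insensitive)."""
    for f in make_suite(dim_multivariate):
        if f.name.lower() == name.lower():
            return f
    raise ConfigError(f"unknown benchmark function {name!r}")


def grid_refine_min(f: BenchmarkFunction, grid_n: int = 400) -> float:
    """Dense-grid minimum of a 2-D function, polished by a local search.

    Evaluates ``grid_n x grid_n`` points over the box, then runs a
    bounded Nelder-Mead refinement from the best grid cell.  Serves as the
    deterministic oracle for the bivariate suite minima.
    """
    if f.dim != 2:
        raise ConfigError("grid_refine_min requires a 2-D function")
    if grid_n < 10:
        raise ConfigError("grid_n must be >= 10")
    xs = np.linspace(f.bounds_low[0], f.bounds_high[0], grid_n)
    ys = np.linspace(f.bounds_low[1], f.bounds_high[1], grid_n)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.stack([xx.ravel(), yy.ravel()], axis=1)
    vals = np.array([f.evaluate(p) for p in pts])
    best = pts[int(np.argmin(vals))]
    res = sp_optimize.minimize(
        f.evaluate,
        best,
        method="Nelder-Mead",
        bounds=list(zip(f.bounds_low, f.bounds_high)),
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
    )
    return float(min(res.fun, vals.min()))


@dataclass
class BenchmarkReport:
    """Min/std of per-run best costs for each (function, algorithm) pair."""

    table: pd.DataFrame
    reps: int
    population: int
    iterations: int


def run_protocol(
    functions: Iterable[BenchmarkFunction],
    algorithms: Sequence[str] = ("teo", "dteo"),
    reps: int = 20,
    population: int = 120,
    iterations: int = 100,
    seed: int = 0,
    paired_seeds: bool = True,
) -> BenchmarkReport:
    """Repeated-minimisation comparison protocol.

    Each algorithm solves each function ``reps`` times (population 120 and
    100 iterations by default) with independent per-rep seeds; the report
    records the minimum and the standard deviation of the ``reps`` best
    costs.  With ``paired_seeds`` the same per-rep seeds are reused across
    algorithms, which sharpens algorithm-vs-algorithm comparisons.
    """
    if reps < 1:
        raise ConfigError("reps must be >= 1")
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(reps)]
    rows = []
    for func in functions:
        for ia, algo in enumerate(algorithms):
            bests = []
            for ir in range(reps):
                run_seed = rep_seeds[ir] if paired_seeds else rep_seeds[ir] + 7919 * ia
                config = OptimizerConfig(
                    bounds_low=func.bounds_low,
                    bounds_high=func.bounds_high,
                    population_size=population,
                    max_iterations=iterations,
                    variant=algo,
                    seed=run_seed,
                )
                result = minimize(func.evaluate, config)
                bests.append(result.best_cost)
            bests = np.asarray(bests)
            rows.append(
                {
                    "function": func.name,
                    "algorithm": algo,
                    "min": float(bests.min()),
                    "std": float(bests.std(ddof=0)),
                    "reps": reps,
                    "population": population,
                    "iterations": iterations,
                    "noisy": func.noisy,
                }
            )
    return BenchmarkReport(
        table=pd.DataFrame(rows), reps=reps, population=population, iterations=iterations
    )
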