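"""Common interface for the bound-constrained population metaheuristics.

All four algorithms (water cycle, flower pollination, cuckoo search,
chicken swarm) share one contract:

* the population is initialized uniformly within the bounds from the run's
  seed;
* every candidate is clipped to the bounds before evaluation;
* a candidate evaluating to NaN/inf is treated as +inf and can never become
  the incumbent best;
* the best-so-far objective is recorded after every iteration, so the
  convergence trace is non-increasing by construction;
* identical config + seed gives bit-identical results.

Objective functions may be *batch* callables mapping an ``(m, d)`` array of
candidate rows to ``(m,)`` values (the fast path used by
:func:`stemfit.metrics.make_objective_fn`) or plain scalar functions of a
single vector; the wrapper detects which on first call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Sequence, Tuple

import numpy as np

from ..errors import DomainError

ALGORITHM_IDS = ("wca", "fpa", "cs", "cso")


@dataclass(frozen=True)
class OptimizerConfig:
    """Protocol knobs: which algorithm, population size, budget, seeding."""

    algorithm_id: str
    n_agents: int = 60
    n_iterations: int = 1800
    n_runs: int = 100
    seed: int = 0
    hyperparameters: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm_id not in ALGORITHM_IDS:
            raise DomainError(
                f"unknown algorithm {self.algorithm_id!r}; "
                f"expected one of {ALGORITHM_IDS}"
            )
        if self.n_agents < 2:
            raise DomainError("n_agents must be >= 2")
        if self.n_iterations < 1:
            raise DomainError("n_iterations must be >= 1")
        if self.n_runs < 1:
            raise DomainError("n_runs must be >= 1")


@dataclass(frozen=True)
class FitResult:
    """Outcome of one optimization run."""

    best_x: np.ndarray
    best_objective: float
    convergence: np.ndarray
    run_index: int
    seed: int

    def __post_init__(self) -> None:
        conv = np.asarray(self.convergence, dtype=float)
        object.__setattr__(self, "convergence", conv)
        object.__setattr__(self, "best_x",
                           np.asarray(self.best_x, dtype=float))
        if conv.size and not np.isclose(
                self.best_objective, conv[-1], rtol=0.0, atol=0.0):
            raise DomainError(
                "best_objective must equal the last convergence entry")
        if np.any(np.diff(conv) > 0.0):
            raise DomainError("convergence history must be non-increasing")


def _parse_bounds(bounds) -> Tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(bounds, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 2:
        lb, ub = arr[:, 0], arr[:, 1]
    elif arr.ndim == 2 and arr.shape[0] == 2:
        lb, ub = arr[0], arr[1]
    else:
        raise DomainError("bounds must be per-dimension [lb, ub] pairs")
    if not (np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))):
        raise DomainError("bounds must be finite")
    if np.any(lb >= ub):
        raise DomainError("each lower bound must be strictly below its upper")
    return lb, ub


def _batchify(fn: Callable) -> Callable[[np.ndarray], np.ndarray]:
    """Adapt scalar or batch objective to a sanitized batch callable."""
    mode: List[str] = []

    def call(x: np.ndarray) -> np.ndarray:
        x2 = np.atleast_2d(np.asarray(x, dtype=float))
        if not mode or mode[0] == "batch":
            try:
                out = np.asarray(fn(x2), dtype=float)
                if out.shape == (x2.shape[0],):
                    if not mode:
                        mode.append("batch")
                    return _sanitize(out)
            except Exception:
                if mode:
                    raise
            if not mode:
                mode.append("scalar")
        return _sanitize(np.array([fn(row) for row in x2], dtype=float))

    return call


def _sanitize(values: np.ndarray) -> np.ndarray:
    out = np.array(values, dtype=float, copy=True)
    out[~np.isfinite(out)] = np.inf
    return out


class _Tracker:
    """Elitist best-so-far bookkeeping shared by all algorithms."""

    def __init__(self) -> None:
        self.best_x: np.ndarray | None = None
        self.best_f = np.inf
        self.history: List[float] = []

    def offer(self, x: np.ndarray, f: np.ndarray) -> None:
        if f.size == 0:
            return
        i = int(np.argmin(f))
        if f[i] < self.best_f:
            self.best_f = float(f[i])
            self.best_x = np.array(x[i], copy=True)

    def tick(self) -> None:
        self.history.append(self.best_f)


def _get_runner(algorithm_id: str):
    # local imports avoid a cycle (algorithm modules import this module)
    from . import cs, cso, fpa, wca

    return {"wca": wca.run, "fpa": fpa.run,
            "cs": cs.run, "cso": cso.run}[algorithm_id]


def minimize(objective_fn: Callable, bounds, config: OptimizerConfig,
             run_index: int = 0, seed: int | None = None) -> FitResult:
    """Run one optimization and return the best agent found."""
    lb, ub = _parse_bounds(bounds)
    run_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(run_seed)
    fn = _batchify(objective_fn)
    tracker = _Tracker()
    runner = _get_runner(config.algorithm_id)
    runner(fn, lb, ub, config.n_agents, config.n_iterations, rng,
           dict(config.hyperparameters), tracker)
    if tracker.best_x is None or not np.isfinite(tracker.best_f):
        raise DomainError(
            "objective returned no finite value for any candidate")
    return FitResult(
        best_x=np.clip(tracker.best_x, lb, ub),
        best_objective=tracker.best_f,
        convergence=np.asarray(tracker.history),
        run_index=run_index,
        seed=run_seed,
    )


def multi_run(objective_fn: Callable, bounds, config: OptimizerConfig,
              on_run: Callable[[FitResult], None] | None = None
              ) -> Tuple[List[FitResult], FitResult]:
    """Independent runs with per-run seeds ``config.seed + k``.

    Returns all runs and the selected best (minimum objective, ties broken
    by lowest run index).  ``on_run`` is invoked with each completed run.
    """
    results = []
    for k in range(config.n_runs):
        result = minimize(objective_fn, bounds, config,
                          run_index=k, seed=config.seed + k)
        if on_run is not None:
            on_run(result)
        results.append(result)
    best = min(results, key=lambda r: (r.best_objective, r.run_index))
    return results, best


def init_population(lb: np.ndarray, ub: np.ndarray, n: int,
                    rng: np.random.Generator) -> np.ndarray:
    return lb + rng.random((n, lb.size)) * (ub - lb)


def clip(x: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> np.ndarray:
    return np.clip(x, lb, ub)
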