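"""Chicken swarm optimization.

The population is re-ranked every ``reorder_period`` iterations into
roosters (best), hens, and chicks; hens follow a group rooster plus a
random swarm-mate, chicks follow their mother hen, and roosters take
self-scaled Gaussian steps whose variance grows when a fitter rival
rooster exists.  Moves are accepted greedily (``greedy`` can be set to 0
for the original unconditional update; the incumbent best is tracked
either way).

Hyperparameters: ``rooster_frac`` (0.15), ``hen_frac`` (0.7),
``mother_frac`` (0.5, fraction of hens that are mothers),
``reorder_period`` (10), ``greedy`` (1).
"""

from __future__ import annotations

import numpy as np

from .base import clip, init_population

_EPS = np.finfo(float).tiny


def _roles(f, n_roosters, n_hens, rng):
    order = np.argsort(f, kind="stable")
    roosters = order[:n_roosters]
    hens = order[n_roosters:n_roosters + n_hens]
    chicks = order[n_roosters + n_hens:]
    group_of_hen = rng.integers(0, n_roosters, hens.size)
    n_mothers = max(1, int(round(0.5 * hens.size))) if chicks.size else 0
    mothers = (rng.choice(hens, size=n_mothers, replace=False)
               if n_mothers else np.empty(0, dtype=int))
    mother_of_chick = (rng.choice(mothers, size=chicks.size)
                       if chicks.size else np.empty(0, dtype=int))
    return roosters, hens, chicks, group_of_hen, mother_of_chick


def _bounded_exp(arg: np.ndarray) -> np.ndarray:
    # inf - inf comparisons between failed candidates yield NaN: treat as 0
    arg = np.nan_to_num(np.asarray(arg, dtype=float),
                        nan=0.0, posinf=50.0, neginf=-50.0)
    return np.exp(np.clip(arg, -50.0, 50.0))


def run(fn, lb, ub, n_agents, n_iterations, rng, hp, tracker) -> None:
    rooster_frac = float(hp.get("rooster_frac", 0.15))
    hen_frac = float(hp.get("hen_frac", 0.7))
    period = int(hp.get("reorder_period", 10))
    greedy = bool(hp.get("greedy", 1))
    dim = lb.size

    n_roosters = max(1, int(round(rooster_frac * n_agents)))
    n_hens = max(1, int(round(hen_frac * n_agents)))
    n_roosters = min(n_roosters, n_agents - 1)
    n_hens = min(n_hens, n_agents - n_roosters)

    x = init_population(lb, ub, n_agents, rng)
    f = fn(x)
    tracker.offer(x, f)
    roles = _roles(f, n_roosters, n_hens, rng)

    for t in range(n_iterations):
        if t > 0 and t % period == 0:
            roles = _roles(f, n_roosters, n_hens, rng)
        roosters, hens, chicks, group_of_hen, mother_of_chick = roles

        new = np.array(x, copy=True)

        # roosters: self-scaled Gaussian steps
        rivals = roosters[rng.integers(0, roosters.size, roosters.size)]
        with np.errstate(invalid="ignore", over="ignore"):
            sigma2 = np.where(
                f[roosters] <= f[rivals], 1.0,
                _bounded_exp((f[rivals] - f[roosters])
                             / (np.abs(f[roosters]) + _EPS)))
        new[roosters] = x[roosters] * (
            1.0 + np.sqrt(sigma2)[:, None]
            * rng.standard_normal((roosters.size, dim)))

        # hens: follow group rooster and a random swarm mate
        if hens.size:
            leader = roosters[group_of_hen]
            others = np.concatenate([roosters, hens])
            mate = others[rng.integers(0, others.size, hens.size)]
            with np.errstate(invalid="ignore", over="ignore"):
                s1 = _bounded_exp((f[hens] - f[leader])
                                  / (np.abs(f[hens]) + _EPS))
                s2 = _bounded_exp(f[mate] - f[hens])
            new[hens] = (x[hens]
                         + s1[:, None] * rng.random((hens.size, dim))
                         * (x[leader] - x[hens])
                         + s2[:, None] * rng.random((hens.size, dim))
                         * (x[mate] - x[hens]))

        # chicks: follow mother
        if chicks.size:
            fl = rng.uniform(0.4, 1.0, (chicks.size, 1))
            new[chicks] = x[chicks] + fl * (x[mother_of_chick] - x[chicks])

        new = clip(new, lb, ub)
        f_new = fn(new)
        tracker.offer(new, f_new)
        if greedy:
            better = f_new < f
            x[better] = new[better]
            f[better] = f_new[better]
        else:
            x, f = new, f_new
        tracker.tick()
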