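"""Flower pollination algorithm.

Each flower either performs global pollination — a Levy flight along its
offset from the incumbent best — with probability ``switch_prob``, or
local pollination, a uniform move along the difference of two random
flowers.  Moves are accepted greedily per flower.

Hyperparameters: ``switch_prob`` (default 0.8), ``levy_exponent``
(default 1.5), ``levy_scale`` (default 0.01).
"""

from __future__ import annotations

import numpy as np

from ._levy import levy_steps
from .base import clip, init_population


def run(fn, lb, ub, n_agents, n_iterations, rng, hp, tracker) -> None:
    p_switch = float(hp.get("switch_prob", 0.8))
    exponent = float(hp.get("levy_exponent", 1.5))
    scale = float(hp.get("levy_scale", 0.01))
    dim = lb.size

    x = init_population(lb, ub, n_agents, rng)
    f = fn(x)
    tracker.offer(x, f)
    best = x[int(np.argmin(f))].copy()

    for _ in range(n_iterations):
        use_global = rng.random(n_agents) < p_switch
        steps = scale * levy_steps(rng, (n_agents, dim), exponent)
        x_global = x + steps * (x - best)
        j = rng.integers(0, n_agents, n_agents)
        k = rng.integers(0, n_agents, n_agents)
        eps = rng.random((n_agents, 1))
        x_local = x + eps * (x[j] - x[k])
        candidate = clip(np.where(use_global[:, None], x_global, x_local),
                         lb, ub)
        f_new = fn(candidate)
        better = f_new < f
        x[better] = candidate[better]
        f[better] = f_new[better]
        tracker.offer(x, f)
        best = x[int(np.argmin(f))].copy()
        tracker.tick()
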