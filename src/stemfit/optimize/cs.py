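"""Cuckoo search with Levy flights.

Each generation: every nest proposes a Levy-flight move around the
incumbent best; each proposal challenges a randomly chosen nest and
replaces it if better.  A fraction ``discovery_prob`` of nest components
is then abandoned and rebuilt by a random differential move, accepted
greedily.

Hyperparameters: ``discovery_prob`` (default 0.25), ``levy_exponent``
(default 1.5), ``levy_scale`` (default 0.01).
"""

from __future__ import annotations

import numpy as np

from ._levy import levy_steps
from .base import clip, init_population


def run(fn, lb, ub, n_agents, n_iterations, rng, hp, tracker) -> None:
    pa = float(hp.get("discovery_prob", 0.25))
    exponent = float(hp.get("levy_exponent", 1.5))
    scale = float(hp.get("levy_scale", 0.01))
    dim = lb.size

    x = init_population(lb, ub, n_agents, rng)
    f = fn(x)
    tracker.offer(x, f)
    best = x[int(np.argmin(f))].copy()

    for _ in range(n_iterations):
        # Levy flights around the best nest
        step = scale * levy_steps(rng, (n_agents, dim), exponent) * (x - best)
        cuckoos = clip(x + step * rng.standard_normal((n_agents, dim)),
                       lb, ub)
        f_c = fn(cuckoos)
        targets = rng.integers(0, n_agents, n_agents)
        for i in range(n_agents):  # sequential: duplicate targets allowed
            t = targets[i]
            if f_c[i] < f[t]:
                x[t] = cuckoos[i]
                f[t] = f_c[i]
        tracker.offer(x, f)

        # abandon a fraction of nests via a differential move
        mask = rng.random((n_agents, dim)) < pa
        p1 = rng.permutation(n_agents)
        p2 = rng.permutation(n_agents)
        moved = clip(x + rng.random((n_agents, 1)) * (x[p1] - x[p2]) * mask,
                     lb, ub)
        f_m = fn(moved)
        better = f_m < f
        x[better] = moved[better]
        f[better] = f_m[better]
        tracker.offer(x, f)

        best = x[int(np.argmin(f))].copy()
        tracker.tick()
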