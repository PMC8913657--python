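"""Water cycle algorithm.

A sorted population is split into one sea (incumbent best), ``n_sr - 1``
rivers, and streams.  Streams flow toward their assigned river (or the
sea) and rivers flow toward the sea, with roles swapping whenever a
follower overtakes its leader.  Raining re-injects diversity in two ways:

* *evaporation*: when a river approaches the sea closer than the
  threshold ``d_max`` (linearly decreased to zero, distances measured in
  bound-normalized coordinates), its streams evaporate and rain down as
  fresh uniform positions;
* *raining near the sea*: each iteration a random half of the sea's own
  streams rain down as Gaussian perturbations of the sea.  The Gaussian
  scale is the current per-dimension stream spread times a success-adapted
  radius (grown when a raindrop beats the sea, shrunk otherwise), which
  turns the canonical fixed-variance raining step into a bound-scale-aware
  local refinement.

Two deliberate departures from the canonical description, both needed for
usable convergence on impedance-fitting landscapes (and switchable via
hyperparameters): flow moves are accepted greedily (``greedy=0`` restores
unconditional moves), and the near-sea raining radius adapts instead of
staying fixed.

Hyperparameters: ``n_sr`` (4), ``d_max`` (1e-16), ``c`` (2.0),
``greedy`` (1), ``rain_prob`` (0.5), ``rain_radius`` (initial, sqrt(0.1)),
``rain_grow`` (1.5), ``rain_shrink`` (0.9).
"""

from __future__ import annotations

import numpy as np

from .base import clip, init_population


def _assign_streams(leader_costs: np.ndarray, n_streams: int) -> np.ndarray:
    """Stream count per leader, proportional to leader quality."""
    n_sr = leader_costs.size
    weight = np.abs(leader_costs - leader_costs.max())
    if not np.isfinite(weight).all() or weight.sum() == 0.0:
        weight = np.ones(n_sr)
    counts = np.floor(weight / weight.sum() * n_streams).astype(int)
    counts[0] += n_streams - counts.sum()  # remainder flows to the sea
    return counts


def run(fn, lb, ub, n_agents, n_iterations, rng, hp, tracker) -> None:
    n_sr = max(2, min(int(hp.get("n_sr", 4)), n_agents - 1))
    d_max = float(hp.get("d_max", 1e-16))
    c = float(hp.get("c", 2.0))
    greedy = bool(hp.get("greedy", 1))
    rain_prob = float(hp.get("rain_prob", 0.5))
    radius = float(hp.get("rain_radius", np.sqrt(0.1)))
    grow = float(hp.get("rain_grow", 1.5))
    shrink = float(hp.get("rain_shrink", 0.9))
    dim = lb.size
    span = ub - lb

    x = init_population(lb, ub, n_agents, rng)
    f = fn(x)
    order = np.argsort(f, kind="stable")
    x, f = x[order], f[order]
    tracker.offer(x, f)

    n_streams = n_agents - n_sr
    counts = _assign_streams(f[:n_sr], n_streams)
    leader_of = np.repeat(np.arange(n_sr), counts)
    sea_rows = n_sr + np.nonzero(leader_of == 0)[0]

    def flow(rows: np.ndarray, leaders: np.ndarray) -> None:
        """Move agents toward their leaders; greedy acceptance by default."""
        if rows.size == 0:
            return
        current = x[rows]
        new = clip(current + rng.random((rows.size, dim)) * c
                   * (leaders - current), lb, ub)
        f_new = fn(new)
        tracker.offer(new, f_new)
        if greedy:
            better = f_new < f[rows]
            x[rows[better]] = new[better]
            f[rows[better]] = f_new[better]
        else:
            x[rows] = new
            f[rows] = f_new

    def promote(follower_rows: np.ndarray, leader: int) -> None:
        if follower_rows.size == 0:
            return
        i = follower_rows[int(np.argmin(f[follower_rows]))]
        if f[i] < f[leader]:
            x[[leader, i]] = x[[i, leader]]
            f[[leader, i]] = f[[i, leader]]

    for _ in range(n_iterations):
        # streams flow toward their leaders; overtakers swap roles
        flow(np.arange(n_sr, n_agents), x[leader_of])
        for j in range(n_sr):
            promote(n_sr + np.nonzero(leader_of == j)[0], j)

        # rivers flow toward the sea
        if n_sr > 1:
            flow(np.arange(1, n_sr), x[0][None, :])
            promote(np.arange(1, n_sr), 0)

        # raining near the sea with success-adapted radius
        drops = sea_rows[rng.random(sea_rows.size) < rain_prob]
        if drops.size:
            spread = np.abs(x[n_sr:] - x[0]).mean(axis=0)
            spread = np.maximum(spread, 1e-14 * span)
            cand = clip(x[0] + radius * spread
                        * rng.standard_normal((drops.size, dim)), lb, ub)
            f_c = fn(cand)
            tracker.offer(cand, f_c)
            radius *= grow if f_c.min() < f[0] else shrink
            radius = float(np.clip(radius, 1e-3, 10.0))
            better = f_c < f[drops]
            x[drops[better]] = cand[better]
            f[drops[better]] = f_c[better]
            promote(drops, 0)

        # evaporation: rivers too close to the sea restart their streams
        for j in range(1, n_sr):
            if np.linalg.norm((x[0] - x[j]) / span) < d_max:
                rows = n_sr + np.nonzero(leader_of == j)[0]
                if rows.size:
                    x[rows] = init_population(lb, ub, rows.size, rng)
                    f[rows] = fn(x[rows])
                    tracker.offer(x[rows], f[rows])

        d_max -= d_max / n_iterations
        tracker.tick()
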