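"""Levy-stable step generator (Mantegna's algorithm)."""

from __future__ import annotations

import math

import numpy as np


def levy_steps(rng: np.random.Generator, shape, exponent: float = 1.5
               ) -> np.ndarray:
    """Heavy-tailed steps with tail index ``exponent`` in (1, 2]."""
    lam = exponent
    sigma = (
        math.gamma(1.0 + lam) * math.sin(math.pi * lam / 2.0)
        / (math.gamma((1.0 + lam) / 2.0) * lam * 2.0 ** ((lam - 1.0) / 2.0))
    ) ** (1.0 / lam)
    u = rng.standard_normal(shape) * sigma
    v = rng.standard_normal(shape)
    return u / np.abs(v) ** (1.0 / lam)
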