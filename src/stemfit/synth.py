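"""Synthetic spectra: grids, model simulation with proportional noise,
and random in-bounds parameter draws.

The instrument-style default sweep is 100 Hz - 100 kHz at 80 points per
decade (241 points); a wider 10 Hz - 100 kHz sweep (321 points) is also
commonly used and available through :func:`make_grid`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .models.closed_forms import model_impedance
from .models.specs import ModelSpec, ParameterVector, get_spec
from .spectra import FrequencyGrid, ImpedanceSpectrum

DEFAULT_F_MIN = 100.0
DEFAULT_F_MAX = 100_000.0
ALT_F_MIN = 10.0
DEFAULT_PPD = 80

#: Orders are drawn away from the degenerate order-0 limit.
_ORDER_FLOOR = 0.05


@dataclass(frozen=True)
class NoiseModel:
    """Proportional complex Gaussian noise: z -> z * (1 + eps),
    eps = sigma_rel * (g1 + j*g2)/sqrt(2) with g1, g2 standard normal."""

    sigma_rel: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_rel < 0.0:
            raise DomainError("sigma_rel must be non-negative")


def make_grid(f_min: float = DEFAULT_F_MIN, f_max: float = DEFAULT_F_MAX,
              points_per_decade: int = DEFAULT_PPD) -> FrequencyGrid:
    """Log-uniform grid including both endpoints."""
    return FrequencyGrid.log_spaced(f_min, f_max, points_per_decade)


def simulate_spectrum(model_id: str, params: ParameterVector,
                      grid: FrequencyGrid,
                      noise: NoiseModel | None = None) -> ImpedanceSpectrum:
    """Evaluate a model and optionally perturb it with proportional noise.

    With ``sigma_rel == 0`` the output equals the noiseless model spectrum
    bit-for-bit.
    """
    clean = model_impedance(model_id, params, grid)
    if noise is None or noise.sigma_rel == 0.0:
        return clean
    rng = np.random.default_rng(noise.seed)
    g = rng.standard_normal((2, grid.n_points))
    eps = noise.sigma_rel * (g[0] + 1j * g[1]) / np.sqrt(2.0)
    return ImpedanceSpectrum(grid=grid, z=clean.z * (1.0 + eps))


def sample_params(spec: ModelSpec | str, seed: int = 0,
                  rng: np.random.Generator | None = None) -> ParameterVector:
    """Uniform in-bounds draw; orders are drawn in [0.05, 1].

    For the cole model the draw is repeated until ``r_o > r_inf`` so the
    relaxation strength is positive.
    """
    if isinstance(spec, str):
        spec = get_spec(spec)
    if rng is None:
        rng = np.random.default_rng(seed)
    is_order = np.array([u == "-" for u in spec.units])
    lb = np.where(is_order, _ORDER_FLOOR, spec.lower_bounds)
    ub = spec.upper_bounds
    for _ in range(1000):
        values = lb + rng.random(spec.n_params) * (ub - lb)
        if spec.model_id == "cole":
            i_o, i_inf = spec.index("r_o"), spec.index("r_inf")
            if values[i_o] <= values[i_inf]:
                continue
        # zero draws are measure-zero but would break the closed forms
        if np.any(values == 0.0):
            continue
        return ParameterVector(spec, values)
    raise DomainError("failed to draw valid parameters")  # pragma: no cover
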