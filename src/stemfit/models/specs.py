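"""Model identifiers, parameter orderings, search bounds, and presets.

The five models and their search boxes:

========== =========================================================
model_id    parameters (search order)
========== =========================================================
cole            alpha, r_inf, r_o, c_alpha
double_cole     alpha, beta, r_inf, r_1, r_2, c_alpha, c_beta
double_shell    alpha, beta, r_1, r_2, r_3, c_alpha, c_beta
stem            alpha, beta, gamma, zeta, lambda, r_o, r_1..r_4,
                c_alpha, c_beta, c_gamma, c_zeta, c_lambda
simplified_stem alpha, beta, gamma, r_o, r_1, r_2,
                c_alpha, c_beta, c_gamma
========== =========================================================

Dispersion orders are dimensionless in [0, 1], resistances in ohm,
pseudo-capacitances in F*s^(order-1) (quoted plainly as F).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ..errors import DomainError

MODEL_IDS = ("cole", "double_cole", "double_shell", "stem", "simplified_stem")

_K = 1e3
_M = 1e6
_G = 1e9
_uF = 1e-6
_nF = 1e-9


@dataclass(frozen=True)
class ModelSpec:
    """One model's name, ordered parameters, units and search bounds."""

    model_id: str
    param_names: tuple
    units: tuple
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray

    def __post_init__(self) -> None:
        lb = np.asarray(self.lower_bounds, dtype=float)
        ub = np.asarray(self.upper_bounds, dtype=float)
        object.__setattr__(self, "lower_bounds", lb)
        object.__setattr__(self, "upper_bounds", ub)
        n = len(self.param_names)
        if not (len(self.units) == lb.size == ub.size == n):
            raise DomainError("inconsistent parameter metadata lengths")
        if np.any(lb >= ub):
            raise DomainError("lower bounds must be strictly below upper")

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def index(self, name: str) -> int:
        return self.param_names.index(name)


def _spec(model_id, rows) -> ModelSpec:
    names, units, lbs, ubs = zip(*rows)
    return ModelSpec(model_id, tuple(names), tuple(units),
                     np.array(lbs), np.array(ubs))


MODEL_SPECS: Mapping[str, ModelSpec] = {
    "cole": _spec("cole", [
        ("alpha", "-", 0.0, 1.0),
        ("r_inf", "ohm", 0.0, 100 * _K),
        ("r_o", "ohm", 0.0, 80 * _M),
        ("c_alpha", "F", 0.0, 3 * _uF),
    ]),
    "double_cole": _spec("double_cole", [
        ("alpha", "-", 0.0, 1.0),
        ("beta", "-", 0.0, 1.0),
        ("r_inf", "ohm", 0.0, 1 * _M),
        ("r_1", "ohm", 0.0, 1 * _M),
        ("r_2", "ohm", 0.0, 1 * _M),
        ("c_alpha", "F", 0.0, 4 * _uF),
        ("c_beta", "F", 0.0, 4 * _uF),
    ]),
    "double_shell": _spec("double_shell", [
        ("alpha", "-", 0.0, 1.0),
        ("beta", "-", 0.0, 1.0),
        ("r_1", "ohm", 0.0, 10 * _M),
        ("r_2", "ohm", 0.0, 10 * _M),
        ("r_3", "ohm", 0.0, 10 * _M),
        ("c_alpha", "F", 0.0, 3 * _uF),
        ("c_beta", "F", 0.0, 3 * _uF),
    ]),
    "stem": _spec("stem", [
        ("alpha", "-", 0.0, 1.0),
        ("beta", "-", 0.0, 1.0),
        ("gamma", "-", 0.0, 1.0),
        ("zeta", "-", 0.0, 1.0),
        ("lambda", "-", 0.0, 1.0),
        ("r_o", "ohm", 0.0, 1 * _G),
        ("r_1", "ohm", 0.0, 1 * _G),
        ("r_2", "ohm", 0.0, 1 * _G),
        ("r_3", "ohm", 0.0, 1 * _G),
        ("r_4", "ohm", 0.0, 1 * _G),
        ("c_alpha", "F", 0.0, 100 * _uF),
        ("c_beta", "F", 0.0, 100 * _uF),
        ("c_gamma", "F", 0.0, 100 * _uF),
        ("c_zeta", "F", 0.0, 100 * _uF),
        ("c_lambda", "F", 0.0, 100 * _uF),
    ]),
    "simplified_stem": _spec("simplified_stem", [
        ("alpha", "-", 0.0, 1.0),
        ("beta", "-", 0.0, 1.0),
        ("gamma", "-", 0.0, 1.0),
        ("r_o", "ohm", 0.0, 100 * _M),
        ("r_1", "ohm", 0.0, 100 * _M),
        ("r_2", "ohm", 0.0, 100 * _M),
        ("c_alpha", "F", 0.0, 10 * _uF),
        ("c_beta", "F", 0.0, 10 * _uF),
        ("c_gamma", "F", 0.0, 10 * _uF),
    ]),
}


def get_spec(model_id: str) -> ModelSpec:
    try:
        return MODEL_SPECS[model_id]
    except KeyError:
        raise DomainError(
            f"unknown model {model_id!r}; expected one of {MODEL_IDS}"
        ) from None


@dataclass(frozen=True)
class ParameterVector:
    """Concrete in-bounds parameter values for one model."""

    spec: ModelSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (self.spec.n_params,):
            raise DomainError(
                f"{self.spec.model_id} expects {self.spec.n_params} "
                f"parameters, got shape {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise DomainError("parameter values must be finite")
        below = v < self.spec.lower_bounds
        above = v > self.spec.upper_bounds
        if np.any(below | above):
            bad = [self.spec.param_names[i]
                   for i in np.nonzero(below | above)[0]]
            raise DomainError(f"parameters out of bounds: {bad}")

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.spec.index(name)])

    def as_dict(self) -> dict:
        return dict(zip(self.spec.param_names, map(float, self.values)))


def make_params(model_id: str, values: Sequence[float]) -> ParameterVector:
    """Validate ``values`` against ``model_id``'s spec."""
    return ParameterVector(get_spec(model_id), np.asarray(values, float))


# Published fitted parameter sets used as example fixtures and CLI presets.
# Only rows with unambiguous printed values are included.
PRESETS: Mapping[str, Mapping[str, tuple]] = {
    "cole": {
        # alpha, r_inf, r_o, c_alpha
        "marjoram5": (0.6647, 5.6834 * _K, 202.28 * _K, 4.2952 * _nF),
        "marjoram10": (0.73, 4.9567 * _K, 558.89 * _K, 1.1493 * _nF),
        "salvia5": (0.7035, 23.987 * _K, 441.99 * _K, 2.7149 * _nF),
        "salvia10": (0.7159, 25.565 * _K, 991.37 * _K, 1.4455 * _nF),
        "lavandula5": (0.5016, 9.4741 * _K, 384.92 * _K, 65.825 * _nF),
        "lavandula10": (0.5562, 2.1391 * _K, 604.51 * _K, 12.135 * _nF),
    },
    "double_cole": {
        # alpha, beta, r_inf, r_1, r_2, c_alpha, c_beta
        "salvia5": (0.5117, 0.7908, 0.0, 143.71 * _K, 316.41 * _K,
                    27.943 * _nF, 1.819 * _nF),
    },
    "double_shell": {
        # alpha, beta, r_1, r_2, r_3, c_alpha, c_beta
        "marjoram10": (0.7813, 0.7044, 1.6228 * _M, 1.8514 * _M,
                       94.061 * _K, 7.9913 * _nF, 1.5936 * _nF),
    },
}


def get_preset(model_id: str, name: str) -> ParameterVector:
    try:
        values = PRESETS[model_id][name]
    except KeyError:
        available = sorted(PRESETS.get(model_id, {}))
        raise DomainError(
            f"no preset {name!r} for model {model_id!r}; "
            f"available: {available}"
        ) from None
    return make_params(model_id, values)
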