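"""Rational closed-form impedance of the five fractional-order models.

Each model has two layers:

* a *batch* evaluator ``<model>_z(values, omega)`` taking an ``(m, p)``
  array of parameter rows and returning ``(m, n)`` complex impedances —
  no validation, used inside optimizer loops where clipped candidates may
  sit on degenerate boundary values (the formulas then yield inf/nan,
  which the optimizer treats as a failed candidate);
* a validated public operation ``<model>_impedance(params, grid)`` on a
  :class:`~stemfit.models.specs.ParameterVector`, enforcing the model's
  mathematical preconditions.

All factored products are evaluated as printed, as products of
``(1 + s^a * R * C)`` terms, which keeps magnitudes well inside double
range across the supported frequency span.
"""

from __future__ import annotations

from typing import Callable, Dict

import numpy as np

from ..errors import DomainError
from ..spectra import FrequencyGrid, ImpedanceSpectrum
from .specs import ParameterVector, get_spec


def _pow(omega: np.ndarray, a: np.ndarray) -> np.ndarray:
    """(j*omega)^a for column vector ``a`` (m,1) against row ``omega`` (n,)."""
    return np.power(omega[None, :], a) * np.exp(1j * (np.pi / 2.0) * a)


def _cols(values: np.ndarray, n: int):
    v = np.asarray(values, dtype=float)
    if v.ndim == 1:
        v = v[None, :]
    if v.shape[-1] != n:
        raise DomainError(f"expected {n} parameters per row, got {v.shape[-1]}")
    return (v[:, k:k + 1] for k in range(n))


def cole_z(values: np.ndarray, omega: np.ndarray) -> np.ndarray:
    alpha, r_inf, r_o, c_a = _cols(values, 4)
    dr = r_o - r_inf
    return r_inf + dr / (1.0 + _pow(omega, alpha) * c_a * dr)


def double_cole_z(values: np.ndarray, omega: np.ndarray) -> np.ndarray:
    alpha, beta, r_inf, r1, r2, c_a, c_b = _cols(values, 7)
    za = r1 / (1.0 + _pow(omega, alpha) * r1 * c_a)
    zb = r2 / (1.0 + _pow(omega, beta) * r2 * c_b)
    return r_inf + za + zb


def double_shell_z(values: np.ndarray, omega: np.ndarray) -> np.ndarray:
    alpha, beta, r1, r2, r3, c_a, c_b = _cols(values, 7)
    sa = _pow(omega, alpha) * c_a
    sb = _pow(omega, beta) * c_b
    num = r1 * (sa * sb * r2 * r3 + sa * r2 + sb * (r2 + r3) + 1.0)
    den = (sa * sb * (r2 * r3 + (r2 + r3) * r1)
           + sb * (r2 + r3) + sa * (r1 + r2) + 1.0)
    return num / den


def stem_z(values: np.ndarray, omega: np.ndarray) -> np.ndarray:
    (alpha, beta, gamma, zeta, lam, r_o, r1, r2, r3, r4,
     c_a, c_b, c_g, c_z, c_l) = _cols(values, 15)
    sa = _pow(omega, alpha) * c_a
    sb = _pow(omega, beta) * c_b
    sg = _pow(omega, gamma) * c_g
    sz = _pow(omega, zeta) * c_z
    sl = _pow(omega, lam) * c_l
    w1, w2, w3, w4 = sa * r1, sb * r2, sg * r3, sz * r4
    num = r_o * (1.0 + w1) * (1.0 + w2) * (1.0 + w3) * (1.0 + w4)
    z_f = (w1 + sa * r_o + 1.0) * (1.0 + w2) * (1.0 + w3) * (1.0 + w4)
    z_k = (r_o * (1.0 + w1)
           * (sb * r3 * sg + sg * r2 * sb + sb + sg)
           * (1.0 + w4))
    z_p = (1.0 + w2) * (1.0 + w3) * (1.0 + w1) * sz * r_o
    z_m = sl * r_o * (1.0 + w1) * (1.0 + w2) * (1.0 + w3) * (1.0 + w4)
    return num / (z_f + z_k + z_p + z_m)


def simplified_stem_z(values: np.ndarray, omega: np.ndarray) -> np.ndarray:
    alpha, beta, gamma, r_o, r1, r2, c_a, c_b, c_g = _cols(values, 9)
    sa = _pow(omega, alpha) * c_a
    sb = _pow(omega, beta) * c_b
    sg = _pow(omega, gamma) * c_g
    z_k = sa * sb * (r1 + r2) + sb + sa
    z_m = sg * (sa * sb * r1 * r2 + sb * r2 + sa * r1 + 1.0)
    return r_o + (1.0 + sb * r2) * (1.0 + sa * r1) / (z_k + z_m)


BATCH_FUNCS: Dict[str, Callable[[np.ndarray, np.ndarray], np.ndarray]] = {
    "cole": cole_z,
    "double_cole": double_cole_z,
    "double_shell": double_shell_z,
    "stem": stem_z,
    "simplified_stem": simplified_stem_z,
}


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise DomainError(message)


def _check_orders(p: ParameterVector, names) -> None:
    for name in names:
        _require(0.0 < p[name] <= 1.0, f"{name} must lie in (0, 1]")


def _check_positive(p: ParameterVector, names) -> None:
    for name in names:
        _require(p[name] > 0.0, f"{name} must be positive")


def _eval(model_id: str, p: ParameterVector,
          grid: FrequencyGrid) -> ImpedanceSpectrum:
    z = BATCH_FUNCS[model_id](p.values, grid.omega)[0]
    return ImpedanceSpectrum(grid=grid, z=z)


def cole_impedance(params: ParameterVector,
                   grid: FrequencyGrid) -> ImpedanceSpectrum:
    """Single-dispersion model: R_inf in series with (R_o - R_inf) || CPE."""
    _require(params.spec.model_id == "cole", "expected cole parameters")
    _require(params["r_o"] > params["r_inf"],
             "relaxation strength requires r_o > r_inf")
    _check_positive(params, ["c_alpha"])
    _check_orders(params, ["alpha"])
    return _eval("cole", params, grid)


def double_cole_impedance(params: ParameterVector,
                          grid: FrequencyGrid) -> ImpedanceSpectrum:
    """Two relaxation sections R_k || CPE_k in series with R_inf."""
    _require(params.spec.model_id == "double_cole",
             "expected double_cole parameters")
    _check_positive(params, ["r_1", "r_2", "c_alpha", "c_beta"])
    _check_orders(params, ["alpha", "beta"])
    return _eval("double_cole", params, grid)


def double_shell_impedance(params: ParameterVector,
                           grid: FrequencyGrid) -> ImpedanceSpectrum:
    """Extracellular R_1 shunting CPE_a + (R_2 || (CPE_b + R_3))."""
    _require(params.spec.model_id == "double_shell",
             "expected double_shell parameters")
    _require(params["r_1"] > 0.0, "r_1 must be positive")
    _check_positive(params, ["c_alpha", "c_beta"])
    _check_orders(params, ["alpha", "beta"])
    return _eval("double_shell", params, grid)


def stem_impedance(params: ParameterVector,
                   grid: FrequencyGrid) -> ImpedanceSpectrum:
    """Six parallel branches: R_o, four series R-CPE pairs, and a bare CPE."""
    _require(params.spec.model_id == "stem", "expected stem parameters")
    _require(params["r_o"] > 0.0, "r_o must be positive")
    _check_positive(params,
                    ["c_alpha", "c_beta", "c_gamma", "c_zeta", "c_lambda"])
    _check_orders(params, ["alpha", "beta", "gamma", "zeta", "lambda"])
    return _eval("stem", params, grid)


def simplified_stem_impedance(params: ParameterVector,
                              grid: FrequencyGrid) -> ImpedanceSpectrum:
    """R_o in series with (R_1+CPE_a) || (R_2+CPE_b) || CPE_g."""
    _require(params.spec.model_id == "simplified_stem",
             "expected simplified_stem parameters")
    _check_positive(params, ["c_alpha", "c_beta", "c_gamma"])
    _check_orders(params, ["alpha", "beta", "gamma"])
    return _eval("simplified_stem", params, grid)


IMPEDANCE_FUNCS = {
    "cole": cole_impedance,
    "double_cole": double_cole_impedance,
    "double_shell": double_shell_impedance,
    "stem": stem_impedance,
    "simplified_stem": simplified_stem_impedance,
}


def model_impedance(model_id: str, params: ParameterVector,
                    grid: FrequencyGrid) -> ImpedanceSpectrum:
    """Dispatch to the named model's validated evaluator."""
    get_spec(model_id)
    return IMPEDANCE_FUNCS[model_id](params, grid)
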