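"""Fitting objective and per-frequency error curves.

The objective is the sum over frequency points of the modulus of the
complex relative error between model and measured impedance,

    sum_i | (Z_model(f_i) - Z_meas(f_i)) / Z_meas(f_i) |,

dimensionless, zero iff the model reproduces the measurement at every
point.  The error curve is the same quantity per point, in percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .errors import DomainError
from .models.closed_forms import BATCH_FUNCS, model_impedance
from .models.specs import ParameterVector
from .spectra import FrequencyGrid, ImpedanceSpectrum


@dataclass(frozen=True)
class ObjectiveValue:
    """Sum of per-point absolute relative errors."""

    value: float
    n_points: int


@dataclass(frozen=True)
class ErrorCurve:
    """Per-frequency relative error in percent."""

    grid: FrequencyGrid
    relative_error_percent: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.relative_error_percent, dtype=float)
        object.__setattr__(self, "relative_error_percent", e)
        if e.shape != (self.grid.n_points,):
            raise DomainError("error curve length must match grid")
        if np.any(e < 0.0) or not np.all(np.isfinite(e)):
            raise DomainError("relative errors must be finite and >= 0")

    @property
    def max(self) -> float:
        return float(self.relative_error_percent.max())

    @property
    def mean(self) -> float:
        return float(self.relative_error_percent.mean())


def _check_measured(measured: ImpedanceSpectrum) -> None:
    if np.any(measured.z == 0.0):
        raise DomainError(
            "measured spectrum contains zero impedance; relative error "
            "is undefined"
        )


def relative_errors(model_z: np.ndarray, measured_z: np.ndarray) -> np.ndarray:
    """Per-point |(Z_model - Z_meas)/Z_meas| (dimensionless)."""
    return np.abs((model_z - measured_z) / measured_z)


def objective(params: ParameterVector, model_id: str,
              measured: ImpedanceSpectrum) -> ObjectiveValue:
    _check_measured(measured)
    model = model_impedance(model_id, params, measured.grid)
    value = float(np.sum(relative_errors(model.z, measured.z)))
    return ObjectiveValue(value=value, n_points=measured.grid.n_points)


def error_curve(params: ParameterVector, model_id: str,
                measured: ImpedanceSpectrum) -> ErrorCurve:
    _check_measured(measured)
    model = model_impedance(model_id, params, measured.grid)
    percent = 100.0 * relative_errors(model.z, measured.z)
    return ErrorCurve(grid=measured.grid, relative_error_percent=percent)


def make_objective_fn(model_id: str, measured: ImpedanceSpectrum
                      ) -> Callable[[np.ndarray], np.ndarray]:
    """Batch objective for optimizers: maps (m, p) parameter rows -> (m,).

    Skips precondition validation (clipped candidates may be degenerate);
    non-finite model values make that row's objective non-finite, which the
    optimizer treats as +inf.
    """
    _check_measured(measured)
    batch = BATCH_FUNCS[model_id]
    omega = measured.grid.omega
    z_meas = measured.z[None, :]

    def fn(values: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            z = batch(np.atleast_2d(values), omega)
            return np.abs((z - z_meas) / z_meas).sum(axis=1)

    return fn


def nyquist_table(spectrum: ImpedanceSpectrum) -> pd.DataFrame:
    """Rows (f, Re Z, -Im Z) — negative imaginary up, per EIS convention."""
    return pd.DataFrame({
        "freq_hz": spectrum.frequencies,
        "z_real_ohm": spectrum.z.real,
        "neg_z_imag_ohm": -spectrum.z.imag,
    })


def error_table(curve: ErrorCurve) -> pd.DataFrame:
    return pd.DataFrame({
        "freq_hz": curve.grid.frequencies,
        "rel_err_percent": curve.relative_error_percent,
    })
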