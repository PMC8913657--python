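"""Constant phase element (CPE).

Impedance ``1/(c * s^order)`` with ``s = j*omega`` on the principal branch:
magnitude ``1/(c * omega^order)``, phase ``-order * pi/2`` at every
frequency.  ``order = 1`` is an ideal capacitor, ``order = 0`` a resistor
of value ``1/c``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import DomainError
from ..spectra import FrequencyGrid, ImpedanceSpectrum


@dataclass(frozen=True)
class CPE:
    """Fractional-order capacitor with pseudo-capacitance ``c`` (F*s^(order-1))."""

    c: float
    order: float

    def __post_init__(self) -> None:
        if not (self.c > 0.0):
            raise DomainError("CPE pseudo-capacitance must be positive")
        if not (0.0 <= self.order <= 1.0):
            raise DomainError("CPE order must lie in [0, 1]")


def s_power(omega: np.ndarray, order) -> np.ndarray:
    """Principal-branch (j*omega)^order; broadcasts ``order`` against ``omega``."""
    order = np.asarray(order, dtype=float)
    return np.power(omega, order) * np.exp(1j * (np.pi / 2.0) * order)


def cpe_impedance(cpe: CPE, grid: FrequencyGrid) -> ImpedanceSpectrum:
    """Evaluate a CPE on a frequency grid."""
    z = 1.0 / (cpe.c * s_power(grid.omega, cpe.order))
    return ImpedanceSpectrum(grid=grid, z=z)
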