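"""Frequency grids and complex impedance spectra.

A :class:`FrequencyGrid` is a strictly increasing, log-uniform sequence of
positive frequencies (Hz) at a fixed number of points per decade.  An
:class:`ImpedanceSpectrum` pairs a grid with one finite complex impedance
value (ohm) per frequency.  The complex frequency used throughout the
package is ``s = j * 2 * pi * f`` (angular convention), with fractional
powers taken on the principal branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, GridError

#: Relative tolerance for the constant-ratio grid invariant.
_RATIO_RTOL = 1e-12


@dataclass(frozen=True)
class FrequencyGrid:
    """Log-uniform frequency grid.

    Parameters
    ----------
    frequencies
        Strictly increasing positive frequencies in Hz.  Consecutive ratios
        must all equal ``10 ** (1 / points_per_decade)``.
    points_per_decade
        Grid density (points per factor-of-ten in frequency).
    """

    frequencies: np.ndarray
    points_per_decade: int

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", f)
        if f.ndim != 1 or f.size == 0:
            raise GridError("frequencies must be a non-empty 1-D array")
        if not np.all(np.isfinite(f)) or np.any(f <= 0.0):
            raise GridError("all frequencies must be finite and positive")
        if np.any(np.diff(f) <= 0.0):
            raise GridError("frequencies must be strictly increasing")
        if self.points_per_decade < 1:
            raise GridError("points_per_decade must be a positive integer")
        if f.size > 1:
            ratios = f[1:] / f[:-1]
            expected = 10.0 ** (1.0 / self.points_per_decade)
            if not np.allclose(ratios, expected, rtol=_RATIO_RTOL, atol=0.0):
                raise GridError(
                    "grid spacing is not 10^(1/points_per_decade); got ratio "
                    f"range [{ratios.min():.17g}, {ratios.max():.17g}], "
                    f"expected {expected:.17g}"
                )

    @classmethod
    def log_spaced(
        cls, f_min: float, f_max: float, points_per_decade: int
    ) -> "FrequencyGrid":
        """Build a grid spanning ``[f_min, f_max]`` inclusive.

        The number of points is ``round(log10(f_max / f_min) * ppd) + 1``.
        The span must be a whole number of grid steps so that both endpoints
        can be included at exact 10^(1/ppd) spacing.
        """
        if not (0.0 < f_min < f_max):
            raise GridError("require 0 < f_min < f_max")
        if points_per_decade < 1:
            raise GridError("points_per_decade must be a positive integer")
        decades = np.log10(f_max / f_min)
        steps = decades * points_per_decade
        n_steps = int(round(steps))
        if n_steps < 1 or abs(steps - n_steps) > 1e-9 * max(1.0, steps):
            raise GridError(
                f"span {f_min} Hz - {f_max} Hz is not a whole number of "
                f"steps at {points_per_decade} points/decade"
            )
        f = np.geomspace(f_min, f_max, n_steps + 1)
        # geomspace guarantees exact endpoints; enforce anyway.
        f[0], f[-1] = f_min, f_max
        return cls(frequencies=f, points_per_decade=points_per_decade)

    @property
    def n_points(self) -> int:
        return int(self.frequencies.size)

    @property
    def omega(self) -> np.ndarray:
        """Angular frequencies 2*pi*f (rad/s)."""
        return 2.0 * np.pi * self.frequencies

    @property
    def s(self) -> np.ndarray:
        """Complex frequency j*omega."""
        return 1j * self.omega

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.n_points


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """A frequency grid with one complex impedance value per point."""

    grid: FrequencyGrid
    z: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=complex)
        object.__setattr__(self, "z", z)
        if z.ndim != 1 or z.size != self.grid.n_points:
            raise DomainError(
                f"impedance array has {z.size} values for "
                f"{self.grid.n_points} frequencies"
            )
        if not np.all(np.isfinite(z)):
            raise DomainError("impedance values must all be finite")

    @property
    def frequencies(self) -> np.ndarray:
        return self.grid.frequencies

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.grid.n_points
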