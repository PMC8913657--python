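"""Circuit-topology impedance oracle.

An independent evaluation path: each model is described as a tree of
resistors, CPEs, series combinations, and parallel combinations, and the
driving-point impedance is computed by recursive series addition of
impedances and parallel addition of admittances.  A CPE with ``c = 0`` is
an open branch (admittance zero); a CPE with ``order = 0`` is the resistor
``1/c``.  This path never uses the rational closed forms, so agreement
between the two is a genuine cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np

from ..errors import DomainError
from ..spectra import FrequencyGrid, ImpedanceSpectrum
from .elements import s_power
from .specs import ParameterVector, get_spec

# --- element tree -----------------------------------------------------------


@dataclass(frozen=True)
class Res:
    """Resistor whose value is the named parameter (or a difference of two)."""

    name: str
    minus: str = ""  # optional parameter subtracted from `name`


@dataclass(frozen=True)
class Cpe:
    """CPE referencing a (c, order) parameter pair by name."""

    c_name: str
    order_name: str


@dataclass(frozen=True)
class Ser:
    parts: Tuple["Node", ...]


@dataclass(frozen=True)
class Par:
    parts: Tuple["Node", ...]


Node = Union[Res, Cpe, Ser, Par]


@dataclass(frozen=True)
class CircuitTopology:
    model_id: str
    root: Node


def _ser(*parts: Node) -> Ser:
    return Ser(tuple(parts))


def _par(*parts: Node) -> Par:
    return Par(tuple(parts))


_TOPOLOGIES = {
    "cole": CircuitTopology("cole", _ser(
        Res("r_inf"),
        _par(Res("r_o", minus="r_inf"), Cpe("c_alpha", "alpha")),
    )),
    "double_cole": CircuitTopology("double_cole", _ser(
        Res("r_inf"),
        _par(Res("r_1"), Cpe("c_alpha", "alpha")),
        _par(Res("r_2"), Cpe("c_beta", "beta")),
    )),
    "double_shell": CircuitTopology("double_shell", _par(
        Res("r_1"),
        _ser(Cpe("c_alpha", "alpha"),
             _par(Res("r_2"), _ser(Cpe("c_beta", "beta"), Res("r_3")))),
    )),
    "stem": CircuitTopology("stem", _par(
        Res("r_o"),
        _ser(Res("r_1"), Cpe("c_alpha", "alpha")),
        _ser(Res("r_2"), Cpe("c_beta", "beta")),
        _ser(Res("r_3"), Cpe("c_gamma", "gamma")),
        _ser(Res("r_4"), Cpe("c_zeta", "zeta")),
        Cpe("c_lambda", "lambda"),
    )),
    "simplified_stem": CircuitTopology("simplified_stem", _ser(
        Res("r_o"),
        _par(_ser(Res("r_1"), Cpe("c_alpha", "alpha")),
             _ser(Res("r_2"), Cpe("c_beta", "beta")),
             Cpe("c_gamma", "gamma")),
    )),
}


def topology_for(model_id: str) -> CircuitTopology:
    get_spec(model_id)  # raises on unknown id
    return _TOPOLOGIES[model_id]


# --- evaluation -------------------------------------------------------------


def _recip(z: np.ndarray) -> np.ndarray:
    """1/z with inf -> 0 and 0 -> inf (open/short conventions)."""
    out = np.empty_like(z)
    open_ = np.isinf(z.real) | np.isinf(z.imag)
    short = z == 0.0
    ok = ~(open_ | short)
    out[open_] = 0.0
    out[short] = complex(np.inf, 0.0)
    out[ok] = 1.0 / z[ok]
    return out


def _eval_node(node: Node, p: ParameterVector, omega: np.ndarray) -> np.ndarray:
    n = omega.size
    if isinstance(node, Res):
        r = p[node.name] - (p[node.minus] if node.minus else 0.0)
        if r < 0.0:
            raise DomainError(
                f"negative resistance {node.name}"
                + (f" - {node.minus}" if node.minus else "")
            )
        return np.full(n, r, dtype=complex)
    if isinstance(node, Cpe):
        c, order = p[node.c_name], p[node.order_name]
        if c == 0.0:  # open branch
            return np.full(n, complex(np.inf, 0.0))
        if order == 0.0:  # degenerate CPE == resistor 1/c
            return np.full(n, 1.0 / c, dtype=complex)
        return 1.0 / (c * s_power(omega, order))
    if isinstance(node, Ser):
        return sum(_eval_node(part, p, omega) for part in node.parts)
    if isinstance(node, Par):
        y = sum(_recip(_eval_node(part, p, omega)) for part in node.parts)
        return _recip(y)
    raise TypeError(f"unknown circuit node {node!r}")  # pragma: no cover


def circuit_oracle_impedance(topology: CircuitTopology,
                             params: ParameterVector,
                             grid: FrequencyGrid) -> ImpedanceSpectrum:
    """Evaluate a topology by series/parallel combination of its elements."""
    if topology.model_id != params.spec.model_id:
        raise DomainError(
            f"topology is for {topology.model_id!r} but parameters are for "
            f"{params.spec.model_id!r}"
        )
    z = _eval_node(topology.root, params, grid.omega)
    return ImpedanceSpectrum(grid=grid, z=z)


def oracle_impedance(model_id: str, params: ParameterVector,
                     grid: FrequencyGrid) -> ImpedanceSpectrum:
    """Shorthand: look up the model's topology and evaluate it."""
    return circuit_oracle_impedance(topology_for(model_id), params, grid)
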