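"""Plain-text readers and writers: spectrum CSV, fit-result documents,
error-curve and convergence CSVs.

The canonical spectrum format is a comma-separated file with header
``freq_hz,z_real_ohm,z_imag_ohm``, ``.`` decimals, and optional ``#``
comment lines.  Fit results are stored as versioned ``key = value``
documents that reload losslessly.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Dict, Union

import numpy as np
import pandas as pd

from .errors import SpectrumFormatError
from .metrics import ErrorCurve, error_table, nyquist_table
from .models.specs import ModelSpec, ParameterVector, get_spec
from .optimize.base import FitResult, OptimizerConfig
from .spectra import FrequencyGrid, ImpedanceSpectrum

PathLike = Union[str, Path]

SPECTRUM_COLUMNS = ("freq_hz", "z_real_ohm", "z_imag_ohm")
RESULT_SCHEMA_VERSION = 1


# --- spectra ----------------------------------------------------------------


def read_spectrum_csv(path: PathLike,
                      points_per_decade: int | None = None
                      ) -> ImpedanceSpectrum:
    """Load and validate a spectrum; rows are sorted by frequency.

    ``points_per_decade`` may be given explicitly; otherwise it is inferred
    from the median consecutive frequency ratio.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    except Exception as exc:
        raise SpectrumFormatError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in SPECTRUM_COLUMNS if c not in df.columns]
    if missing:
        raise SpectrumFormatError(
            f"{path}: missing columns {missing}; expected header "
            f"{','.join(SPECTRUM_COLUMNS)}")
    data = {}
    for col in SPECTRUM_COLUMNS:
        values = pd.to_numeric(df[col], errors="coerce").to_numpy(float)
        bad = np.nonzero(~np.isfinite(values))[0]
        if bad.size:
            raise SpectrumFormatError(
                f"{path}: non-numeric value in column {col!r}, data row "
                f"{int(bad[0]) + 1}")
        data[col] = values
    f = data["freq_hz"]
    if f.size == 0:
        raise SpectrumFormatError(f"{path}: no data rows")
    nonpos = np.nonzero(f <= 0.0)[0]
    if nonpos.size:
        raise SpectrumFormatError(
            f"{path}: non-positive frequency in data row "
            f"{int(nonpos[0]) + 1}")
    order = np.argsort(f, kind="stable")
    f = f[order]
    dup = np.nonzero(np.diff(f) == 0.0)[0]
    if dup.size:
        raise SpectrumFormatError(
            f"{path}: duplicate frequency {f[dup[0]]:g} Hz")
    z = data["z_real_ohm"][order] + 1j * data["z_imag_ohm"][order]
    if points_per_decade is None:
        ratio = np.median(f[1:] / f[:-1]) if f.size > 1 else 10.0
        points_per_decade = max(1, int(round(1.0 / np.log10(ratio))))
    grid = FrequencyGrid(frequencies=f, points_per_decade=points_per_decade)
    return ImpedanceSpectrum(grid=grid, z=z)


def write_spectrum_csv(path: PathLike, spectrum: ImpedanceSpectrum,
                       header_comment: str = "") -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in filter(None, header_comment.splitlines()):
            fh.write(f"# {line}\n")
        fh.write(",".join(SPECTRUM_COLUMNS) + "\n")
        for f, z in zip(spectrum.frequencies, spectrum.z):
            fh.write(f"{float(f)!r},{float(z.real)!r},{float(z.imag)!r}\n")


# --- curves -----------------------------------------------------------------


def write_nyquist_csv(path: PathLike, spectrum: ImpedanceSpectrum) -> None:
    nyquist_table(spectrum).to_csv(path, index=False)


def write_error_curve_csv(path: PathLike, curve: ErrorCurve) -> None:
    error_table(curve).to_csv(path, index=False)


def write_convergence_csv(path: PathLike, result: FitResult) -> None:
    pd.DataFrame({
        "iteration": np.arange(result.convergence.size),
        "best_objective": result.convergence,
    }).to_csv(path, index=False)


# --- fit-result documents ---------------------------------------------------


def write_fit_result(path: PathLike, result: FitResult, spec: ModelSpec,
                     config: OptimizerConfig | None = None,
                     convergence_file: str = "") -> None:
    """Serialize a fit as a ``key = value`` text document (lossless)."""
    lines = [
        f"schema_version = {RESULT_SCHEMA_VERSION}",
        f"model_id = {spec.model_id}",
        f"best_objective = {float(result.best_objective)!r}",
        f"run_index = {result.run_index}",
        f"run_seed = {result.seed}",
    ]
    if config is not None:
        lines += [
            f"algorithm_id = {config.algorithm_id}",
            f"n_agents = {config.n_agents}",
            f"n_iterations = {config.n_iterations}",
            f"n_runs = {config.n_runs}",
            f"base_seed = {config.seed}",
        ]
    for name, unit, value in zip(spec.param_names, spec.units,
                                 result.best_x):
        lines.append(f"param.{name} = {float(value)!r}")
        lines.append(f"unit.{name} = {unit}")
    if convergence_file:
        lines.append(f"convergence_file = {convergence_file}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fit_result(path: PathLike) -> Dict[str, object]:
    """Parse a fit-result document.

    Returns a dict with ``model_id``, ``params`` (a ParameterVector),
    ``best_objective`` and any config echo keys present.
    """
    raw: Dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise SpectrumFormatError(
                f"{path}: line {lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        raw[key] = value
    if raw.get("schema_version") != str(RESULT_SCHEMA_VERSION):
        raise SpectrumFormatError(
            f"{path}: unsupported schema_version {raw.get('schema_version')}")
    spec = get_spec(raw["model_id"])
    values = []
    for name in spec.param_names:
        key = f"param.{name}"
        if key not in raw:
            raise SpectrumFormatError(f"{path}: missing {key}")
        values.append(float(raw[key]))
    out: Dict[str, object] = {
        "model_id": spec.model_id,
        "params": ParameterVector(spec, np.array(values)),
        "best_objective": float(raw["best_objective"]),
    }
    for key in ("algorithm_id",):
        if key in raw:
            out[key] = raw[key]
    for key in ("run_index", "run_seed", "n_agents", "n_iterations",
                "n_runs", "base_seed"):
        if key in raw:
            out[key] = int(raw[key])
    if "convergence_file" in raw:
        out["convergence_file"] = raw["convergence_file"]
    return out
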