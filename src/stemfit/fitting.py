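"""Model-aware fitting layer: extract parameters from a spectrum and
compare models on one measurement."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .metrics import ErrorCurve, make_objective_fn, relative_errors
from .models.closed_forms import BATCH_FUNCS
from .models.specs import MODEL_IDS, ParameterVector, get_spec
from .optimize.base import FitResult, OptimizerConfig, multi_run
from .spectra import ImpedanceSpectrum


@dataclass(frozen=True)
class ModelFitResult:
    """A model fitted to one spectrum: selected best run plus all runs."""

    model_id: str
    params: ParameterVector
    best: FitResult
    runs: Tuple[FitResult, ...]
    error_curve: ErrorCurve

    @property
    def best_objective(self) -> float:
        return self.best.best_objective

    @property
    def max_error_percent(self) -> float:
        return self.error_curve.max

    @property
    def mean_error_percent(self) -> float:
        return self.error_curve.mean


def _unvalidated_error_curve(model_id: str, values: np.ndarray,
                             measured: ImpedanceSpectrum) -> ErrorCurve:
    # fitted vectors may sit on degenerate boundary values the validated
    # evaluators reject; the raw batch form is defined there
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        z = BATCH_FUNCS[model_id](values, measured.grid.omega)[0]
    percent = 100.0 * relative_errors(z, measured.z)
    return ErrorCurve(grid=measured.grid, relative_error_percent=percent)


def fit_model(measured: ImpedanceSpectrum, model_id: str,
              config: OptimizerConfig) -> ModelFitResult:
    """Extract one model's parameters from a spectrum via ``multi_run``."""
    spec = get_spec(model_id)
    bounds = np.column_stack([spec.lower_bounds, spec.upper_bounds])
    fn = make_objective_fn(model_id, measured)
    runs, best = multi_run(fn, bounds, config)
    params = ParameterVector(spec, best.best_x)
    curve = _unvalidated_error_curve(model_id, best.best_x, measured)
    return ModelFitResult(model_id=model_id, params=params, best=best,
                          runs=tuple(runs), error_curve=curve)


@dataclass(frozen=True)
class ComparisonReport:
    """Per-model fit summaries ranked by max per-frequency error."""

    fits: Dict[str, ModelFitResult]
    ranking: Tuple[str, ...]

    def summary_rows(self) -> List[dict]:
        rows = []
        for rank, model_id in enumerate(self.ranking, 1):
            fit = self.fits[model_id]
            rows.append({
                "rank": rank,
                "model_id": model_id,
                "best_objective": fit.best_objective,
                "max_error_percent": fit.max_error_percent,
                "mean_error_percent": fit.mean_error_percent,
            })
        return rows


def compare_models(measured: ImpedanceSpectrum, config: OptimizerConfig,
                   model_ids: Sequence[str] = MODEL_IDS) -> ComparisonReport:
    """Fit each model under the same protocol and rank by max % error."""
    fits = {m: fit_model(measured, m, config) for m in model_ids}
    ranking = tuple(sorted(
        fits, key=lambda m: (fits[m].max_error_percent, m)))
    return ComparisonReport(fits=fits, ranking=ranking)
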