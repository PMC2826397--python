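"""Variance-normalized squared-error scoring of predicted measurements.

The metric for a set of predicted cells is

    sum_i (x_i - p_i)^2 / (sigma_tech^2 + (cv * x_i)^2)

where ``x_i`` is the withheld true measurement and ``p_i`` the prediction.
The denominator is an estimate of the measurement variance: the squared
technical noise floor plus the squared biological variability, the latter
parameterized as coefficient-of-variation times the true measurement.
Defaults are sigma_tech = 300 (detector sensitivity floor) and cv = 0.8;
both are configurable because the convention (SD vs variance) is a choice.

Significance is assessed against a column-resampling null: missing cells
are filled by sampling, with replacement, from the observed values in the
same analyte column, preserving each analyte's dynamic range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats import MeasurementTable, ValidationError
from .null_models import fit_stretched_exponential, tail_pvalue

__all__ = [
    "ErrorModel",
    "normalized_squared_error",
    "resample_null",
    "response_pvalue",
    "N_PHOSPHOPROTEINS",
    "N_CYTOKINES",
    "N_CELL_TYPES",
    "N_SCORED_TIME_POINTS",
    "N_TEST_CONDITIONS",
    "N_STIMULUS_LEVELS",
    "N_INHIBITOR_LEVELS",
    "solicited_prediction_count",
    "perturbation_grid_size",
]

# Challenge-structure constants: analytes measured per subchallenge, cell
# types, scored post-baseline time points, held-out perturbation conditions,
# and the stimulus/inhibitor grid (7 of each, plus "none").
N_PHOSPHOPROTEINS = 17
N_CYTOKINES = 20
N_CELL_TYPES = 2
N_SCORED_TIME_POINTS = 2
N_TEST_CONDITIONS = 7
N_STIMULUS_LEVELS = 8
N_INHIBITOR_LEVELS = 8


def solicited_prediction_count(n_analytes: int) -> int:
    """Prediction cells solicited for a subchallenge with ``n_analytes``."""
    return n_analytes * N_CELL_TYPES * N_SCORED_TIME_POINTS * N_TEST_CONDITIONS


def perturbation_grid_size() -> int:
    """Size of the full stimulus x inhibitor combination grid."""
    return N_STIMULUS_LEVELS * N_INHIBITOR_LEVELS


@dataclass(frozen=True)
class ErrorModel:
    """Technical noise floor and biological coefficient of variation."""

    sigma_tech: float = 300.0
    cv: float = 0.8

    def __post_init__(self) -> None:
        if self.sigma_tech <= 0:
            raise ValidationError(f"sigma_tech must be > 0, got {self.sigma_tech}")
        if self.cv <= 0:
            raise ValidationError(f"cv must be > 0, got {self.cv}")

    def variance(self, truth):
        truth = np.asarray(truth, dtype=float)
        return self.sigma_tech**2 + (self.cv * truth) ** 2


def _target_cells(obs: MeasurementTable) -> list[tuple[str, str]]:
    cells = obs.masked_cells()
    if not cells:
        raise ValidationError("observation table has no masked (target) cells")
    return cells


def normalized_squared_error(
    pred: MeasurementTable, obs: MeasurementTable, model: ErrorModel | None = None
) -> float:
    """Sum of variance-normalized squared errors over the masked cells of
    ``obs``.  ``obs`` must carry the true value at every masked cell and
    ``pred`` a prediction for it."""
    model = model or ErrorModel()
    cells = _target_cells(obs)
    missing_truth = [c for c in cells if not np.isfinite(obs.values.at[c])]
    if missing_truth:
        raise ValidationError(f"no true value for masked cells: {missing_truth}")
    missing_pred = [
        c
        for c in cells
        if c[0] not in pred.values.index
        or c[1] not in pred.values.columns
        or not np.isfinite(pred.values.at[c])
    ]
    if missing_pred:
        raise ValidationError(f"missing prediction for masked cells: {missing_pred}")
    x = np.array([obs.values.at[c] for c in cells], dtype=float)
    p = np.array([pred.values.at[c] for c in cells], dtype=float)
    return float(np.sum((x - p) ** 2 / model.variance(x)))


def resample_null(
    table: MeasurementTable,
    n_reps: int,
    seed: int,
    model: ErrorModel | None = None,
) -> np.ndarray:
    """Metric values for ``n_reps`` random fill-ins of the masked cells.

    Each masked cell is filled by drawing, with replacement, from the
    observed (unmasked) values in its analyte column; the filled table is
    scored against the true values, which ``table`` must carry at the
    masked cells.
    """
    model = model or ErrorModel()
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    cells = _target_cells(table)
    rng = np.random.default_rng(seed)
    values = table.values
    mask = table.mask
    total = np.zeros(n_reps)
    for analyte in table.analytes:
        col_mask = mask[analyte].to_numpy(dtype=bool)
        if not col_mask.any():
            continue
        observed = values[analyte].to_numpy(dtype=float)[~col_mask]
        observed = observed[np.isfinite(observed)]
        if observed.size == 0:
            raise ValidationError(
                f"column {analyte!r} has masked cells but no observed values"
            )
        truth = values[analyte].to_numpy(dtype=float)[col_mask]
        if not np.isfinite(truth).all():
            raise ValidationError(f"column {analyte!r} missing truth at masked cell")
        draws = rng.choice(observed, size=(n_reps, truth.size), replace=True)
        total += np.sum((truth - draws) ** 2 / model.variance(truth), axis=1)
    return total


def response_pvalue(
    observed_metric: float, null_sample, fit_tails: bool = False
) -> float:
    """Lower-tail p-value of an observed metric (small error = good).

    Without ``fit_tails`` this is the add-one-smoothed empirical fraction
    ``(#{null <= observed} + 1) / (n + 1)``; with ``fit_tails`` the
    stretched-exponential fit to the null sample is integrated instead
    (requires >= 1000 null values).
    """
    null_sample = np.asarray(null_sample, dtype=float)
    if null_sample.size < 1:
        raise ValidationError("empty null sample")
    if np.ptp(null_sample) == 0:
        raise ValidationError("degenerate null sample (zero variance)")
    observed = float(observed_metric)
    if np.isnan(observed):
        raise ValidationError("observed metric is NaN")
    if observed == np.inf:
        return 1.0
    if fit_tails:
        fit = fit_stretched_exponential(null_sample)
        return tail_pvalue(fit, observed, side="lower")
    r = int(np.sum(null_sample <= observed))
    return (r + 1) / (null_sample.size + 1)
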