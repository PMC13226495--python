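"""Model validation: leave-one-out cross-validation and external test sets.

Leave-one-out (LOO) refits the chosen model family on n-1 observations
and predicts the held-out one, once per observation:

    Q2_LOO = 1 - sum_j (y_j - yhat_{j,LOO})^2 / sum_j (y_j - ybar)^2

By default ``ybar`` is the mean of all n actual values (the standard
convention); per-fold training means are available behind the
``mean="training"`` switch for sensitivity checks.  RMSECV and MAE are
the root-mean-square and mean-absolute LOO prediction errors.

External validation evaluates an already-fitted model on compounds that
took no part in the fit and reports per-compound residuals
(actual - predicted) along with their RMSE and MAE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .regression import RegressionModel, fit_model, predict

_MEAN_CONVENTIONS = ("full", "training")


@dataclass(frozen=True)
class LOOReport:
    """Leave-one-out summary for one descriptor/property pair."""

    q2: float
    rmsecv: float
    mae: float
    residuals: tuple[float, ...]
    family: str
    mean_convention: str = "full"


@dataclass(frozen=True)
class ExternalReport:
    """External test-set summary: per-compound residuals and errors."""

    residuals: tuple[float, ...]
    rmse: float
    mae: float


def loo_cv(
    x: Sequence[float],
    y: Sequence[float],
    family: str,
    *,
    mean: str = "full",
) -> LOOReport:
    """Leave-one-out cross-validation of one single-descriptor family.

    Needs enough observations that every fold is fittable (n >= p + 3).
    """
    if mean not in _MEAN_CONVENTIONS:
        raise ValueError(f"mean convention must be one of {_MEAN_CONVENTIONS}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    p = 2 if family == "quadratic" else 1
    if n < p + 3:
        raise ValueError(f"need at least {p + 3} observations for LOO with {p} terms")
    residuals = np.empty(n)
    denom_terms = np.empty(n)
    for j in range(n):
        mask = np.ones(n, dtype=bool)
        mask[j] = False
        try:
            fold = fit_model(x[mask], y[mask], family)
        except ValueError as exc:
            raise ValueError(f"LOO fold {j} (holding out observation {j}) failed: {exc}") from exc
        residuals[j] = y[j] - predict(fold, x[j])
        ybar = y.mean() if mean == "full" else y[mask].mean()
        denom_terms[j] = (y[j] - ybar) ** 2
    press = float(residuals @ residuals)
    denom = float(denom_terms.sum())
    q2 = 1.0 - press / denom
    return LOOReport(
        q2=q2,
        rmsecv=math.sqrt(press / n),
        mae=float(np.abs(residuals).mean()),
        residuals=tuple(residuals),
        family=family,
        mean_convention=mean,
    )


def external_validate(
    model: RegressionModel,
    x_test: Sequence[float],
    y_test: Sequence[float],
) -> ExternalReport:
    """Evaluate a fitted model on an external test set."""
    x = np.asarray(x_test, dtype=float)
    y = np.asarray(y_test, dtype=float)
    if x.size == 0:
        raise ValueError("external test set is empty")
    if x.shape != y.shape:
        raise ValueError("x_test and y_test differ in length")
    residuals = y - np.atleast_1d(predict(model, x))
    return ExternalReport(
        residuals=tuple(float(r) for r in residuals),
        rmse=float(np.sqrt((residuals**2).mean())),
        mae=float(np.abs(residuals).mean()),
    )
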