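"""Prediction-quality statistics and the dependent-correlation test."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

MSEP_DEFINITIONS = ("squared_difference", "regression_residual")


@dataclass(frozen=True)
class QualityMetrics:
    """Per-validation-set quality summary of one model."""

    r_pa: float | None
    bias_slope: float | None
    msep: float
    msep_residual: float
    n: int


@dataclass(frozen=True)
class CorrelationComparison:
    r12: float
    r13: float
    r23: float
    n: int
    t_stat: float
    df: int
    p_value: float


def _aligned(predicted, realized) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(realized, dtype=float)
    if p.shape != r.shape or p.ndim != 1:
        raise ValueError("predicted and realized must be aligned 1-D vectors")
    if p.size < 3:
        raise ValueError(f"need at least 3 validation lines, got {p.size}")
    return p, r


def predictive_ability(predicted, realized) -> float | None:
    """Pearson correlation between predictions and realized values.

    Returns ``None`` (logged) if either vector has zero variance.
    """
    p, r = _aligned(predicted, realized)
    if np.std(p) == 0.0 or np.std(r) == 0.0:
        logger.warning("predictive ability undefined: zero variance input")
        return None
    return float(np.corrcoef(p, r)[0, 1])


def bias_regression(predicted, realized) -> float | None:
    """OLS slope of realized on predicted; 1 means empirically unbiased."""
    p, r = _aligned(predicted, realized)
    var_p = np.var(p)
    if var_p == 0.0:
        logger.warning("bias slope undefined: predictions have zero variance")
        return None
    return float(np.cov(p, r, ddof=1)[0, 1] / np.var(p, ddof=1))


def msep(predicted, realized, definition: str = "squared_difference") -> float:
    """Mean squared error of prediction.

    ``squared_difference``: mean((realized - predicted)^2), combining bias
    and precision.  ``regression_residual``: mean squared OLS residual of
    realized on predicted (slope bias removed).
    """
    p, r = _aligned(predicted, realized)
    if definition == "squared_difference":
        return float(np.mean((r - p) ** 2))
    if definition == "regression_residual":
        slope, intercept = np.polyfit(p, r, 1)
        resid = r - (intercept + slope * p)
        return float(np.mean(resid**2))
    raise ValueError(f"unknown MSEP definition {definition!r}; use {MSEP_DEFINITIONS}")


def quality_metrics(predicted, realized) -> QualityMetrics:
    p, r = _aligned(predicted, realized)
    return QualityMetrics(
        r_pa=predictive_ability(p, r),
        bias_slope=bias_regression(p, r),
        msep=msep(p, r, "squared_difference"),
        msep_residual=msep(p, r, "regression_residual"),
        n=p.size,
    )


def hotelling_williams(r12: float, r13: float, r23: float, n: int) -> CorrelationComparison:
    """Williams' t (Steiger's form) for two dependent correlations.

    Tests ``H0: rho12 = rho13`` where variables 2 and 3 (two predictors)
    share variable 1 (the realized values).  Two-sided p from Student t
    with ``n - 3`` degrees of freedom.
    """
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    for name, r in (("r12", r12), ("r13", r13), ("r23", r23)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name} must lie strictly in (-1, 1), got {r}")
    det = 1.0 - r12**2 - r13**2 - r23**2 + 2.0 * r12 * r13 * r23
    if det <= 0.0:
        raise ValueError(f"degenerate correlation matrix (|R| = {det:g})")
    rbar = 0.5 * (r12 + r13)
    df = n - 3
    denom = 2.0 * ((n - 1) / (n - 3)) * det + rbar**2 * (1.0 - r23) ** 3
    t = (r12 - r13) * math.sqrt((n - 1) * (1.0 + r23) / denom)
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return CorrelationComparison(r12, r13, r23, n, float(t), df, min(p, 1.0))


def compare_predictors(
    realized, predicted_1, predicted_2
) -> CorrelationComparison:
    """Hotelling-Williams comparison of two predictors of the same realized values."""
    y = np.asarray(realized, dtype=float)
    p1 = np.asarray(predicted_1, dtype=float)
    p2 = np.asarray(predicted_2, dtype=float)
    if not (y.shape == p1.shape == p2.shape):
        raise ValueError("all three vectors must be aligned")
    r12 = float(np.corrcoef(y, p1)[0, 1])
    r13 = float(np.corrcoef(y, p2)[0, 1])
    r23 = float(np.corrcoef(p1, p2)[0, 1])
    return hotelling_williams(r12, r13, r23, y.size)
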