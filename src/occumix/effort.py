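"""Confidence-of-absence calculator.

If a species is present and each survey detects it independently with
probability p, the chance of at least one detection in K surveys is the
cumulative detection probability p* = 1 - (1 - p)^K. Inverting this gives
the minimum number of repeat surveys needed before non-detection supports
absence at a chosen confidence level. Mapping a fitted detection-effort
relationship (per-survey p as a function of the number of artificial cover
objects) through that inverse yields survey-planning curves.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .data import ValidationError
from .occupancy import OccupancyFit, predict_detection

__all__ = ["cumulative_detection", "min_surveys", "effort_curve"]


def cumulative_detection(p: float, k: int) -> float:
    """p* = 1 - (1 - p)^K: probability of >= 1 detection in K surveys."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError("p must be in [0, 1]")
    if k < 0 or k != int(k):
        raise ValidationError("K must be a nonnegative integer")
    return 1.0 - (1.0 - p) ** int(k)


def min_surveys(p: float, confidence: float) -> int:
    """Smallest K with 1 - (1 - p)^K >= confidence.

    Closed form: ceil(ln(1 - confidence) / ln(1 - p)). A p of zero can
    never reach the target, and p = 1 needs a single survey.
    """
    if not 0.0 < confidence < 1.0:
        raise ValidationError("confidence must be in (0, 1)")
    if not 0.0 < p <= 1.0:
        raise ValidationError(f"confidence {confidence} unreachable at p={p}")
    if p == 1.0:
        return 1
    k = math.ceil(math.log(1.0 - confidence) / math.log(1.0 - p))
    # guard against floating-point grazing of the boundary
    while cumulative_detection(p, k) < confidence:  # pragma: no cover
        k += 1
    while k > 1 and cumulative_detection(p, k - 1) >= confidence:
        k -= 1
    return k


def effort_curve(
    fit: OccupancyFit,
    aco_grid,
    confidences=(0.80, 0.90, 0.95),
    aco_name: str = "acos",
) -> pd.DataFrame:
    """Minimum-survey requirements across a grid of cover-object effort.

    For each grid point the fitted detection model gives p with a 95% CI;
    ``min_surveys`` maps these through to K at each confidence level. The
    mapping is anti-monotone, so the upper K band comes from the lower p
    bound and vice versa. Grid values beyond the observed effort range are
    permitted but flagged as extrapolation.
    """
    aco_grid = np.asarray(aco_grid, float)
    if aco_name not in [t.name for t in fit._det_terms]:
        raise ValidationError(
            f"fit has no detection covariate {aco_name!r}; an effort curve "
            "needs a detection-effort relationship"
        )
    if aco_name in fit.covariates.scaling:
        mean, sd = fit.covariates.scaling[aco_name]
        observed_max = mean + sd * float(np.max(
            fit.covariates.site[aco_name].to_numpy(float)))
        if np.any(aco_grid > observed_max):
            warnings.warn(
                f"effort grid extends beyond the observed maximum "
                f"({observed_max:.0f} cover objects): extrapolating", RuntimeWarning)
    rows = []
    for aco in aco_grid:
        est = predict_detection(fit, {aco_name: float(aco)})
        row = {"acos": float(aco), "p": est.point, "p_lo": est.lower, "p_hi": est.upper}
        for c in confidences:
            tag = f"{int(round(100 * c))}"
            row[f"k_{tag}"] = min_surveys(est.point, c) if est.point > 0 else np.inf
            if est.lower is not None:
                row[f"k_{tag}_lo"] = min_surveys(est.upper, c)
                row[f"k_{tag}_hi"] = (min_surveys(est.lower, c)
                                      if est.lower > 0 else np.inf)
        rows.append(row)
    return pd.DataFrame(rows)
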