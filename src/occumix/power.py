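"""Power analysis for detecting an occupancy decline under imperfect detection.

Two independent survey periods each sample S sites with K visits per site.
The occupancy estimator from a single-season model with constant p has
asymptotic per-site variance factor

    v(psi, p, K) = psi * [ (1 - psi) + (1 - p*) / (p* - K p (1 - p)^(K-1)) ],

where p* = 1 - (1 - p)^K; imperfect detection inflates the binomial
variance psi(1 - psi) through the second term, which vanishes as p -> 1.
For a one-tailed z-test of a proportional decline R (psi2 = psi1 (1 - R))
at significance alpha and power 1 - beta, the required number of sites per
period is

    S = ceil[ (z_{1-alpha} + z_{1-beta})^2 (v1 + v2) / (psi1 - psi2)^2 ].

The grid calculator maps a fitted detection-effort relationship and a
reference-length occupancy estimate across cover-object effort, visit
numbers and decline sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data import ValidationError
from .effort import cumulative_detection
from .occupancy import OccupancyFit, predict_detection, predict_occupancy

__all__ = ["PowerSpec", "occupancy_variance_factor", "sites_required", "power_grid"]


def occupancy_variance_factor(psi: float, p: float, k: int) -> float:
    """Per-site asymptotic variance factor of the occupancy MLE.

    Defined only when the design is informative enough that
    p* > K p (1 - p)^(K-1); below that threshold the single-season model
    cannot separate occupancy from detection and the variance is unbounded.
    At p = 1 the factor reduces exactly to the binomial psi(1 - psi).
    """
    if not 0.0 < psi < 1.0:
        raise ValidationError("psi must be in (0, 1)")
    if not 0.0 < p <= 1.0:
        raise ValidationError("p must be in (0, 1]")
    if k < 1:
        raise ValidationError("K must be >= 1")
    if p == 1.0:
        return psi * (1.0 - psi)
    p_star = cumulative_detection(p, k)
    info = p_star - k * p * (1.0 - p) ** (k - 1)
    if info <= 1e-10 * p_star:  # K = 1 gives info = 0 up to rounding
        raise ValidationError(
            f"non-identifiable design: p*({k}) = {p_star:.4f} does not exceed "
            f"K p (1-p)^(K-1) = {p_star - info:.4f}"
        )
    return psi * ((1.0 - psi) + (1.0 - p_star) / info)


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the two-period decline test.

    ``psi1`` is initial occupancy at the reference transect length, ``decline``
    the proportional drop R (so psi2 = psi1 (1 - R)), ``p`` per-survey
    detection, ``k`` visits per site per period, ``alpha`` the one-tailed
    significance level and ``power`` the target 1 - beta.
    """

    psi1: float
    decline: float
    p: float
    k: int
    alpha: float = 0.05
    power: float = 0.80
    two_tailed: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.psi1 < 1.0:
            raise ValidationError("psi1 must be in (0, 1)")
        if not 0.0 < self.decline < 1.0:
            raise ValidationError("decline R must be in (0, 1)")
        if not 0.0 < self.alpha < 1.0 or not 0.0 < self.power < 1.0:
            raise ValidationError("alpha and power must be in (0, 1)")

    @property
    def psi2(self) -> float:
        return self.psi1 * (1.0 - self.decline)


def sites_required(spec: PowerSpec) -> int:
    """Sites per period needed to detect the decline at the target power."""
    alpha = spec.alpha / 2.0 if spec.two_tailed else spec.alpha
    z = norm.ppf(1.0 - alpha) + norm.ppf(spec.power)
    v1 = occupancy_variance_factor(spec.psi1, spec.p, spec.k)
    v2 = occupancy_variance_factor(spec.psi2, spec.p, spec.k)
    effect = spec.psi1 - spec.psi2
    return math.ceil(z**2 * (v1 + v2) / effect**2)


def power_grid(
    fit: OccupancyFit,
    aco_grid=tuple(range(0, 101, 10)),
    declines=(0.15, 0.30, 0.50),
    visits=(4, 6, 8),
    alpha: float = 0.05,
    power: float = 0.80,
    reference_length_km: float = 1.5,
    aco_name: str = "acos",
) -> pd.DataFrame:
    """Required sites across effort, decline and visit grids.

    psi1 comes from the fitted occupancy model evaluated at the reference
    transect length; p from the fitted detection-effort relationship at each
    cover-object grid point. CI bands propagate the p and psi interval
    endpoints jointly through ``sites_required`` (S falls as either rises,
    so the optimistic band pairs the upper endpoints). Grid cells where the
    design is non-identifiable are recorded with ``attainable=False`` rather
    than dropped.
    """
    psi_est = predict_occupancy(fit, reference_length_km)
    rows = []
    for aco in aco_grid:
        p_est = predict_detection(fit, {aco_name: float(aco)})
        for r in declines:
            for k in visits:
                row = {"acos": float(aco), "decline": r, "k": int(k),
                       "psi1": psi_est.point, "p": p_est.point}
                try:
                    row["sites"] = sites_required(PowerSpec(
                        psi1=psi_est.point, decline=r, p=p_est.point, k=k,
                        alpha=alpha, power=power))
                    row["attainable"] = True
                except ValidationError:
                    row["sites"] = np.nan
                    row["attainable"] = False
                for tag, p_end, psi_end in (
                    ("sites_lo", p_est.upper, psi_est.upper),
                    ("sites_hi", p_est.lower, psi_est.lower),
                ):
                    if p_end is None or psi_end is None:
                        continue
                    try:
                        row[tag] = sites_required(PowerSpec(
                            psi1=psi_end, decline=r, p=p_end, k=k,
                            alpha=alpha, power=power))
                    except ValidationError:
                        row[tag] = np.nan
                rows.append(row)
    return pd.DataFrame(rows)
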