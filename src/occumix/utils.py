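"""Shared numerics: link functions, delta-method intervals, optimisation helpers."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit  # noqa: F401  (re-exported)
from scipy.stats import norm

__all__ = [
    "ProbabilityEstimate",
    "expit",
    "logit",
    "linear_predictor_interval",
    "multistart_minimize",
    "numerical_hessian",
    "covariance_from_hessian",
]


@dataclass(frozen=True)
class ProbabilityEstimate:
    """A probability with a delta-method standard error and 95% CI.

    The interval is computed on the linear-predictor (logit) scale and
    back-transformed, so both endpoints stay inside [0, 1] and the interval
    is asymmetric around the point estimate, as is conventional for
    occupancy/detection summaries.
    """

    point: float
    se: float | None = None
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.point <= 1.0:
            raise ValueError(f"probability {self.point} outside [0, 1]")
        if self.lower is not None and self.upper is not None:
            if not (self.lower - 1e-12 <= self.point <= self.upper + 1e-12):
                raise ValueError("interval does not bracket the point estimate")


def linear_predictor_interval(
    eta: float, var_eta: float, level: float = 0.95
) -> ProbabilityEstimate:
    """Back-transform a normal interval on the logit scale to a probability."""
    if var_eta < 0 or not np.isfinite(var_eta):
        return ProbabilityEstimate(float(expit(eta)))
    se_eta = float(np.sqrt(var_eta))
    z = norm.ppf(0.5 + level / 2.0)
    point = float(expit(eta))
    lo = float(expit(eta - z * se_eta))
    hi = float(expit(eta + z * se_eta))
    # delta-method SE on the probability scale: dp/deta = p(1-p)
    se = se_eta * point * (1.0 - point)
    return ProbabilityEstimate(point, se, lo, hi)


def multistart_minimize(objective, n_params, seed=0, n_restarts=4, start=None, spread=0.5):
    """Quasi-Newton minimisation from a zero (or supplied) start plus seeded
    random restarts; returns the best scipy OptimizeResult.

    A warm ``start`` with ``n_restarts=0`` is used inside bootstrap loops
    where the previous optimum is an excellent initial value.
    """
    rng = np.random.default_rng(seed)
    starts = [np.zeros(n_params) if start is None else np.asarray(start, float)]
    starts += [rng.normal(0.0, spread, n_params) for _ in range(n_restarts)]
    best = None
    for x0 in starts:
        try:
            res = minimize(
                objective,
                x0,
                method="L-BFGS-B",
                options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 1000},
            )
        except (FloatingPointError, np.linalg.LinAlgError):  # pragma: no cover
            continue
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    if best is None:
        raise RuntimeError("all optimisation starts failed")
    return best


def numerical_hessian(f, x, step=1e-4):
    """Central finite-difference Hessian of a scalar function."""
    x = np.asarray(x, float)
    k = x.size
    h = step * np.maximum(1.0, np.abs(x))
    hess = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return hess


def covariance_from_hessian(hess):
    """Invert an observed-information matrix, falling back to a pseudo-inverse
    (with a warning) when the Hessian is singular or indefinite."""
    try:
        vcov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        warnings.warn("observed information singular; using pseudo-inverse", RuntimeWarning)
        return np.linalg.pinv(hess)
    if np.any(np.diag(vcov) < 0):
        warnings.warn(
            "observed information not positive definite at the optimum", RuntimeWarning
        )
    return vcov
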