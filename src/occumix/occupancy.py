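"""Single-season site-occupancy model with imperfect detection.

The model: each site-year i is occupied with probability psi_i, and an
occupied site yields a detection on visit t with probability p_it,
independently across visits and sites. With detection history y_it in
{0, 1, missing},

    logit(p_it)  = alpha0 + alpha . x_it
    logit(psi_i) = beta0 + beta . z_i + ln(L_i)      [optional offset]

and the site likelihood marginalises the latent occupancy state:

    L_i = psi_i * prod_t p_it^y_it (1 - p_it)^(1 - y_it)
          + (1 - psi_i) * 1{all y_it = 0}.

The log transect-length offset makes beta0 the log-odds of occupancy *per
kilometre of transect*: a transect of length L is occupied with probability
invlogit(beta0 + ln L), which increases monotonically with L and equals the
per-km value at L = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_expit

from . import _design
from .data import CovariateSet, DetectionHistory, SchemaError, ValidationError
from .utils import (
    ProbabilityEstimate,
    covariance_from_hessian,
    expit,
    linear_predictor_interval,
    multistart_minimize,
    numerical_hessian,
)

__all__ = [
    "OccupancyModelSpec",
    "OccupancyFit",
    "occupancy_negloglik",
    "fit_occupancy",
    "predict_occupancy",
    "predict_detection",
]


@dataclass(frozen=True)
class OccupancyModelSpec:
    """Which covariates act on detection and occupancy, and whether the
    occupancy linear predictor carries a log transect-length offset.

    ``max_one_covariate`` enforces the single-covariate-per-parameter
    candidate-set rule used for small samples; relax it for richer models.
    """

    detection: tuple = ()
    occupancy: tuple = ()
    length_offset: bool = True
    max_one_covariate: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "detection", tuple(self.detection))
        object.__setattr__(self, "occupancy", tuple(self.occupancy))
        if self.max_one_covariate and (len(self.detection) > 1 or len(self.occupancy) > 1):
            raise ValidationError(
                "model set allows at most one covariate per parameter; "
                "pass max_one_covariate=False to relax"
            )


def _prepare(history, covariates, spec):
    y = history.values
    mask = history.observed
    det_terms = _design.resolve_terms(covariates, spec.detection)
    occ_terms = _design.resolve_terms(covariates, spec.occupancy)
    x_det = _design.visit_matrix(covariates, det_terms, y.shape)
    x_occ = _design.site_matrix(covariates, occ_terms, y.shape[0])
    if spec.length_offset:
        if "transect_km" not in covariates.site.columns:
            raise SchemaError("length offset requested but no 'transect_km' covariate")
        offset = np.log(covariates.site["transect_km"].to_numpy(float))
    else:
        offset = np.zeros(y.shape[0])
    if not (np.all(np.isfinite(x_det)) and np.all(np.isfinite(x_occ)) and
            np.all(np.isfinite(offset))):
        raise ValidationError("non-finite covariate or offset value")
    return y, mask, det_terms, occ_terms, x_det, x_occ, offset


def _negloglik_arrays(params, y, mask, x_det, x_occ, offset):
    n_det = x_det.shape[2]
    alpha = params[:n_det]
    beta = params[n_det:]
    eta_p = x_det @ alpha                       # (n, T)
    eta_psi = x_occ @ beta + offset             # (n,)
    y0 = np.nan_to_num(y)
    # per-visit Bernoulli log-likelihood conditional on occupancy
    ll_visits = y0 * log_expit(eta_p) + (1.0 - y0) * log_expit(-eta_p)
    ll_det = np.where(mask, ll_visits, 0.0).sum(axis=1)
    log_psi = log_expit(eta_psi)
    log_1mpsi = log_expit(-eta_psi)
    all_zero = np.where(mask, y0, 0.0).sum(axis=1) == 0
    occupied_branch = log_psi + ll_det
    site_ll = np.where(
        all_zero, np.logaddexp(occupied_branch, log_1mpsi), occupied_branch
    )
    return -float(site_ll.sum())


def occupancy_negloglik(params, history, covariates, spec) -> float:
    """Negative log-likelihood of the occupancy model at ``params``.

    ``params`` stacks the detection coefficients (intercept first) followed
    by the occupancy coefficients. Missing visits contribute nothing.
    """
    y, mask, det_terms, occ_terms, x_det, x_occ, offset = _prepare(history, covariates, spec)
    k = x_det.shape[2] + x_occ.shape[1]
    params = np.asarray(params, float)
    if params.size != k:
        raise ValidationError(f"expected {k} parameters, got {params.size}")
    return _negloglik_arrays(params, y, mask, x_det, x_occ, offset)


@dataclass
class OccupancyFit:
    """A maximised occupancy model: coefficients, curvature and provenance."""

    spec: OccupancyModelSpec
    params: np.ndarray
    det_names: list
    occ_names: list
    vcov: np.ndarray
    loglik: float
    n_params: int
    converged: bool
    history: DetectionHistory = field(repr=False)
    covariates: CovariateSet = field(repr=False)
    _det_terms: list = field(repr=False, default_factory=list)
    _occ_terms: list = field(repr=False, default_factory=list)

    @property
    def det_coefs(self) -> np.ndarray:
        return self.params[: len(self.det_names)]

    @property
    def occ_coefs(self) -> np.ndarray:
        return self.params[len(self.det_names):]

    @property
    def occ_slice(self) -> slice:
        return slice(len(self.det_names), self.n_params)

    def _arrays(self):
        return _prepare(self.history, self.covariates, self.spec)

    def fitted_p(self) -> np.ndarray:
        """(n_sites, max_visits) fitted per-visit detection probabilities."""
        _, _, _, _, x_det, _, _ = self._arrays()
        return expit(x_det @ self.det_coefs)

    def fitted_psi(self) -> np.ndarray:
        """(n_sites,) fitted occupancy probabilities (offset included)."""
        _, _, _, _, _, x_occ, offset = self._arrays()
        return expit(x_occ @ self.occ_coefs + offset)

    def expected_cells(self):
        """Unconditional mean and variance of each observed site-visit cell,
        for Pearson residual-based goodness of fit. E[y] = psi * p and y is
        Bernoulli, so Var[y] = E[y](1 - E[y])."""
        mean = self.fitted_psi()[:, None] * self.fitted_p()
        return mean, mean * (1.0 - mean), self.history.values, self.history.observed

    def simulate(self, rng) -> DetectionHistory:
        """Draw a replicate detection history from the fitted model."""
        psi = self.fitted_psi()
        p = self.fitted_p()
        z = rng.random(psi.shape) < psi
        y = (rng.random(p.shape) < p) & z[:, None]
        values = np.where(self.history.observed, y.astype(float), np.nan)
        return DetectionHistory(values)

    def refit(self, history: DetectionHistory, seed=0) -> "OccupancyFit":
        """Refit to new data warm-starting from this optimum (bootstrap path)."""
        return fit_occupancy(
            history, self.covariates, self.spec, seed=seed,
            n_restarts=0, start=self.params, hessian=False,
        )


def fit_occupancy(
    history: DetectionHistory,
    covariates: CovariateSet,
    spec: OccupancyModelSpec,
    seed: int = 0,
    n_restarts: int = 4,
    start=None,
    hessian: bool = True,
) -> OccupancyFit:
    """Maximum-likelihood fit with seeded multi-start quasi-Newton search.

    The covariance matrix is the inverse observed information (finite-
    difference Hessian at the optimum). Degenerate data — no detections
    anywhere, or a detection on every scheduled visit — put the MLE on the
    parameter-space boundary and trigger a warning rather than an error.
    """
    y, mask, det_terms, occ_terms, x_det, x_occ, offset = _prepare(history, covariates, spec)
    y0 = np.where(mask, np.nan_to_num(y), 0.0)
    if y0.sum() == 0:
        warnings.warn("no detections in any history: estimates lie on the boundary",
                      RuntimeWarning)
    elif np.all(y0[mask] == 1.0):
        warnings.warn("every scheduled visit is a detection: boundary estimates",
                      RuntimeWarning)

    def objective(params):
        return _negloglik_arrays(params, y, mask, x_det, x_occ, offset)

    res = multistart_minimize(objective, x_det.shape[2] + x_occ.shape[1],
                              seed=seed, n_restarts=n_restarts, start=start)
    params = np.asarray(res.x, float)
    k = params.size
    vcov = np.full((k, k), np.nan)
    if hessian:
        hess = numerical_hessian(objective, params)
        vcov = covariance_from_hessian(hess)
    converged = bool(res.success) and np.isfinite(res.fun)
    if not converged:
        warnings.warn("occupancy fit did not converge", RuntimeWarning)
    return OccupancyFit(
        spec=spec,
        params=params,
        det_names=_design.column_names(det_terms, "p(intercept)"),
        occ_names=_design.column_names(occ_terms, "psi(intercept)"),
        vcov=vcov,
        loglik=-float(res.fun),
        n_params=k,
        converged=converged,
        history=history,
        covariates=covariates,
        _det_terms=det_terms,
        _occ_terms=occ_terms,
    )


def _coerce_occ_params(fit_or_params):
    """Accept an OccupancyFit or a bare occupancy coefficient vector/scalar."""
    if isinstance(fit_or_params, OccupancyFit):
        beta = fit_or_params.occ_coefs
        sl = fit_or_params.occ_slice
        vcov = fit_or_params.vcov[sl, sl]
        return fit_or_params, beta, vcov
    beta = np.atleast_1d(np.asarray(fit_or_params, float))
    return None, beta, None


def predict_occupancy(
    fit_or_params, transect_length: float, site_covariates: dict | None = None
) -> ProbabilityEstimate:
    """Occupancy probability of a transect of the given length (km).

    With the log-length offset the point estimate is
    invlogit(beta0 + beta.z + ln L). Confidence limits are computed on the
    linear-predictor scale and back-transformed (delta method), which keeps
    them inside [0, 1]. Raw coefficient vectors are accepted in place of a
    fit, in which case no interval is available.
    """
    if transect_length <= 0:
        raise ValidationError("transect length must be positive")
    fit, beta, vcov = _coerce_occ_params(fit_or_params)
    if fit is not None:
        terms = fit._occ_terms
        row = _design.prediction_row(terms, site_covariates or {}, fit.covariates)
        offset = np.log(transect_length) if fit.spec.length_offset else 0.0
    else:
        z = np.asarray([] if site_covariates is None else site_covariates, float)
        row = np.concatenate([[1.0], np.atleast_1d(z)]) if z.size else np.array([1.0])
        offset = np.log(transect_length)
    eta = float(row @ beta) + offset
    if vcov is None or not np.all(np.isfinite(vcov)):
        return ProbabilityEstimate(float(expit(eta)))
    return linear_predictor_interval(eta, float(row @ vcov @ row))


def predict_detection(fit_or_params, visit_covariates: dict | None = None) -> ProbabilityEstimate:
    """Per-survey detection probability at a new design point.

    Covariate values are given in raw units (e.g. ``{"acos": 10}``) and are
    projected onto the training scale via the stored (mean, sd) metadata.
    """
    if isinstance(fit_or_params, OccupancyFit):
        fit = fit_or_params
        terms = fit._det_terms
        row = _design.prediction_row(terms, visit_covariates or {}, fit.covariates)
        alpha = fit.det_coefs
        sl = slice(0, len(fit.det_names))
        vcov = fit.vcov[sl, sl]
        eta = float(row @ alpha)
        if not np.all(np.isfinite(vcov)):
            return ProbabilityEstimate(float(expit(eta)))
        return linear_predictor_interval(eta, float(row @ vcov @ row))
    alpha = np.atleast_1d(np.asarray(fit_or_params, float))
    z = np.asarray([] if visit_covariates is None else visit_covariates, float)
    row = np.concatenate([[1.0], np.atleast_1d(z)]) if z.size else np.array([1.0])
    return ProbabilityEstimate(float(expit(float(row @ alpha))))
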