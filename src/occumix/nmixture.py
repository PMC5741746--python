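"""Binomial N-mixture abundance model for repeated counts.

Each site-year i hosts a latent abundance N_i drawn from a count mixture
(Poisson, negative binomial, or zero-inflated Poisson) with site mean

    log(lambda_i) = b0 + b . z_i + ln(L_i)       [optional offset]

and each visit's count is a binomial thinning of N_i:

    y_it | N_i ~ Binomial(N_i, p_it),   logit(p_it) = a0 + a . x_it.

The marginal likelihood truncates the infinite sum over N at Kmax
(default 50, with an automatic sufficiency check):

    L_i = sum_{N=0}^{Kmax} f(N; lambda_i, theta) prod_t Bin(y_it | N, p_it).

With the log-length offset, b0 is log abundance per kilometre of transect.
Empirical-Bayes machinery turns a converged fit into per-site posterior
abundance distributions (whose mean is the "best unbiased predictor") and a
parametric-bootstrap interval for total abundance across transects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_expit, logsumexp
from scipy.stats import binom, nbinom, poisson

from . import _design
from .data import CountMatrix, CovariateSet, SchemaError, ValidationError
from .utils import covariance_from_hessian, expit, multistart_minimize, numerical_hessian

__all__ = [
    "MIXTURES",
    "NMixtureModelSpec",
    "NMixtureFit",
    "PosteriorAbundance",
    "TotalAbundance",
    "nmixture_negloglik",
    "fit_nmixture",
    "eb_posterior",
    "total_abundance",
    "raise_lower_bound",
]

MIXTURES = ("poisson", "nb", "zip")


@dataclass(frozen=True)
class NMixtureModelSpec:
    """Mixture choice, covariates, offset and truncation bound.

    ``fixed_detection`` pins p at a known value (no detection parameters are
    estimated); it exists for degenerate closed-form checks such as perfect
    detection.
    """

    mixture: str = "poisson"
    abundance: tuple = ()
    detection: tuple = ()
    length_offset: bool = True
    kmax: int = 50
    fixed_detection: float | None = None
    max_one_covariate: bool = True

    def __post_init__(self) -> None:
        if self.mixture not in MIXTURES:
            raise ValidationError(f"mixture must be one of {MIXTURES}")
        object.__setattr__(self, "abundance", tuple(self.abundance))
        object.__setattr__(self, "detection", tuple(self.detection))
        if self.kmax < 1:
            raise ValidationError("kmax must be a positive integer")
        if self.max_one_covariate and (len(self.detection) > 1 or len(self.abundance) > 1):
            raise ValidationError(
                "model set allows at most one covariate per parameter; "
                "pass max_one_covariate=False to relax"
            )
        if self.fixed_detection is not None and self.detection:
            raise ValidationError("fixed_detection excludes detection covariates")

    @property
    def n_extra(self) -> int:
        """NB dispersion / ZIP zero-inflation parameters, on free scales."""
        return 0 if self.mixture == "poisson" else 1


def _prepare(counts, covariates, spec):
    y = counts.values
    mask = counts.observed
    if np.nanmax(np.where(mask, y, 0.0), initial=0.0) > spec.kmax:
        raise ValidationError("observed count exceeds the truncation bound kmax")
    ab_terms = _design.resolve_terms(covariates, spec.abundance)
    det_terms = _design.resolve_terms(covariates, spec.detection)
    x_ab = _design.site_matrix(covariates, ab_terms, y.shape[0])
    x_det = _design.visit_matrix(covariates, det_terms, y.shape)
    if spec.length_offset:
        if "transect_km" not in covariates.site.columns:
            raise SchemaError("length offset requested but no 'transect_km' covariate")
        offset = np.log(covariates.site["transect_km"].to_numpy(float))
    else:
        offset = np.zeros(y.shape[0])
    return y, mask, det_terms, ab_terms, x_det, x_ab, offset


def _split(params, spec, n_det, n_ab):
    if spec.fixed_detection is not None:
        n_det = 0
    alpha = params[:n_det]
    beta = params[n_det:n_det + n_ab]
    extra = params[n_det + n_ab:]
    return alpha, beta, extra


def _mixture_logpmf(grid, lam, spec, extra):
    """log f(N; lambda, theta) on the (n_sites, kmax+1) grid."""
    if spec.mixture == "poisson":
        return poisson.logpmf(grid[None, :], lam[:, None])
    if spec.mixture == "nb":
        r = np.exp(extra[0])
        return nbinom.logpmf(grid[None, :], r, r / (r + lam[:, None]))
    # zero-inflated Poisson: point mass at zero with weight pi
    log_pi = log_expit(extra[0])
    log_1mpi = log_expit(-extra[0])
    base = log_1mpi + poisson.logpmf(grid[None, :], lam[:, None])
    at_zero = np.full_like(base, -np.inf)
    at_zero[:, 0] = log_pi
    return np.logaddexp(at_zero, base)


def _mixture_moments(lam, spec, extra):
    """Mean and variance of N under the fitted mixture."""
    if spec.mixture == "poisson":
        return lam, lam
    if spec.mixture == "nb":
        r = np.exp(extra[0])
        return lam, lam + lam**2 / r
    pi = expit(extra[0])
    mean = (1.0 - pi) * lam
    var = (1.0 - pi) * lam * (1.0 + pi * lam)
    return mean, var


def _site_loglik_matrix(params, y, mask, x_det, x_ab, offset, spec):
    """(n_sites, kmax+1) matrix of log f(N) + log P(y_i | N)."""
    n, t_max = y.shape
    n_det = x_det.shape[2]
    alpha, beta, extra = _split(np.asarray(params, float), spec, n_det, x_ab.shape[1])
    if spec.fixed_detection is not None:
        p = np.full((n, t_max), float(spec.fixed_detection))
    else:
        p = expit(x_det @ alpha)
    lam = np.exp(x_ab @ beta + offset)
    grid = np.arange(spec.kmax + 1)
    prior = _mixture_logpmf(grid, lam, spec, extra)           # (n, K+1)
    y0 = np.where(mask, np.nan_to_num(y), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        obs = binom.logpmf(y0[:, None, :], grid[None, :, None], p[:, None, :])
    obs = np.where(mask[:, None, :], obs, 0.0)                # (n, K+1, T)
    return prior + obs.sum(axis=2), p, lam, extra


def nmixture_negloglik(params, counts, covariates, spec) -> float:
    """Negative log marginal likelihood, summing N out up to ``spec.kmax``."""
    y, mask, det_terms, ab_terms, x_det, x_ab, offset = _prepare(counts, covariates, spec)
    k = ((0 if spec.fixed_detection is not None else x_det.shape[2])
         + x_ab.shape[1] + spec.n_extra)
    params = np.asarray(params, float)
    if params.size != k:
        raise ValidationError(f"expected {k} parameters, got {params.size}")
    joint, _, _, _ = _site_loglik_matrix(params, y, mask, x_det, x_ab, offset, spec)
    return -float(logsumexp(joint, axis=1).sum())


@dataclass
class NMixtureFit:
    """A maximised N-mixture model."""

    spec: NMixtureModelSpec
    params: np.ndarray
    det_names: list
    ab_names: list
    extra_names: list
    vcov: np.ndarray
    loglik: float
    n_params: int
    converged: bool
    counts: CountMatrix = field(repr=False)
    covariates: CovariateSet = field(repr=False)
    kmax_delta: float = 0.0
    _det_terms: list = field(repr=False, default_factory=list)
    _ab_terms: list = field(repr=False, default_factory=list)

    def _arrays(self):
        return _prepare(self.counts, self.covariates, self.spec)

    def _pieces(self):
        y, mask, _, _, x_det, x_ab, offset = self._arrays()
        return _site_loglik_matrix(self.params, y, mask, x_det, x_ab, offset, self.spec)

    @property
    def det_coefs(self) -> np.ndarray:
        return self.params[: len(self.det_names)]

    @property
    def ab_coefs(self) -> np.ndarray:
        n_det = len(self.det_names)
        return self.params[n_det:n_det + len(self.ab_names)]

    def fitted_p(self) -> np.ndarray:
        return self._pieces()[1]

    def fitted_lambda(self) -> np.ndarray:
        return self._pieces()[2]

    def expected_cells(self):
        """Cell mean E[y] = E[N] p and marginal count variance
        Var[y] = p(1-p) E[N] + p^2 Var[N] under the fitted mixture."""
        _, p, lam, extra = self._pieces()
        mean_n, var_n = _mixture_moments(lam, self.spec, extra)
        mean = mean_n[:, None] * p
        var = p * (1.0 - p) * mean_n[:, None] + p**2 * var_n[:, None]
        return mean, var, self.counts.values, self.counts.observed

    def simulate(self, rng) -> CountMatrix:
        """Draw a replicate count matrix from the fitted model (closure held:
        one N per site, binomially thinned at each visit)."""
        _, p, lam, extra = self._pieces()
        n = lam.size
        if self.spec.mixture == "poisson":
            big_n = rng.poisson(lam)
        elif self.spec.mixture == "nb":
            r = np.exp(extra[0])
            big_n = rng.negative_binomial(r, r / (r + lam))
        else:
            big_n = np.where(rng.random(n) < expit(extra[0]), 0, rng.poisson(lam))
        y = rng.binomial(big_n[:, None], p)
        values = np.where(self.counts.observed, y.astype(float), np.nan)
        return CountMatrix(values)

    def refit(self, counts: CountMatrix, seed=0) -> "NMixtureFit":
        return fit_nmixture(
            counts, self.covariates, self.spec, seed=seed,
            n_restarts=0, start=self.params, hessian=False,
        )


def fit_nmixture(
    counts: CountMatrix,
    covariates: CovariateSet,
    spec: NMixtureModelSpec,
    seed: int = 0,
    n_restarts: int = 4,
    start=None,
    hessian: bool = True,
) -> NMixtureFit:
    """Maximum-likelihood N-mixture fit with multi-start and honest flags.

    The negative-binomial dispersion is estimated as log(size) and the
    zero-inflation weight as logit(pi), both unconstrained; a dispersion
    estimate on the boundary (size -> infinity, i.e. the Poisson limit, or
    size -> 0) is flagged because such fits are known to be unstable.
    """
    y, mask, det_terms, ab_terms, x_det, x_ab, offset = _prepare(counts, covariates, spec)
    if np.nansum(np.where(mask, y, 0.0)) == 0:
        warnings.warn("all counts are zero: abundance lies on the boundary", RuntimeWarning)

    def objective(params):
        joint, _, _, _ = _site_loglik_matrix(params, y, mask, x_det, x_ab, offset, spec)
        return -float(logsumexp(joint, axis=1).sum())

    n_det = 0 if spec.fixed_detection is not None else x_det.shape[2]
    k = n_det + x_ab.shape[1] + spec.n_extra
    res = multistart_minimize(objective, k, seed=seed, n_restarts=n_restarts, start=start)
    params = np.asarray(res.x, float)
    converged = bool(res.success) and np.isfinite(res.fun)
    if not converged:
        warnings.warn("N-mixture fit did not converge", RuntimeWarning)
    if spec.mixture == "nb" and abs(params[-1]) > np.log(1e6):
        warnings.warn("negative-binomial dispersion on the boundary; "
                      "estimates may be unreliable", RuntimeWarning)

    # truncation sufficiency: doubling kmax should not move the likelihood
    spec2 = NMixtureModelSpec(
        mixture=spec.mixture, abundance=spec.abundance, detection=spec.detection,
        length_offset=spec.length_offset, kmax=2 * spec.kmax,
        fixed_detection=spec.fixed_detection, max_one_covariate=spec.max_one_covariate,
    )
    joint2, _, _, _ = _site_loglik_matrix(params, y, mask, x_det, x_ab, offset, spec2)
    kmax_delta = abs(-float(logsumexp(joint2, axis=1).sum()) - float(res.fun))
    if kmax_delta > 1e-6:
        warnings.warn(
            f"kmax={spec.kmax} may truncate the abundance sum (dNLL={kmax_delta:.2e} "
            "when doubled)", RuntimeWarning)

    vcov = np.full((k, k), np.nan)
    if hessian:
        vcov = covariance_from_hessian(numerical_hessian(objective, params))
    det_names = [] if spec.fixed_detection is not None else _design.column_names(
        det_terms, "p(intercept)")
    extra_names = {"poisson": [], "nb": ["log_size"], "zip": ["logit_zero_inflation"]}
    return NMixtureFit(
        spec=spec,
        params=params,
        det_names=det_names,
        ab_names=_design.column_names(ab_terms, "lambda(intercept)"),
        extra_names=extra_names[spec.mixture],
        vcov=vcov,
        loglik=-float(res.fun),
        n_params=k,
        converged=converged,
        counts=counts,
        covariates=covariates,
        kmax_delta=kmax_delta,
        _det_terms=det_terms,
        _ab_terms=ab_terms,
    )


@dataclass(frozen=True)
class PosteriorAbundance:
    """Per-site posterior of latent abundance N given the data and fit.

    ``mean`` is the empirical best unbiased predictor (BUP); the interval is
    the central 95% posterior interval on the integer support.
    """

    probs: np.ndarray   # (n_sites, kmax + 1)
    mean: np.ndarray
    mode: np.ndarray
    lower: np.ndarray
    upper: np.ndarray


def eb_posterior(fit: NMixtureFit) -> PosteriorAbundance:
    """Empirical-Bayes posterior P(N_i = n | y_i) over n = 0..kmax.

    The posterior is proportional to the mixture prior times the binomial
    likelihood of the site's counts; support below the maximum observed
    count carries zero probability, so the posterior mean never falls below
    the largest count actually seen.
    """
    if not fit.converged:
        raise ValidationError("empirical-Bayes posterior requires a converged fit")
    joint, _, _, _ = fit._pieces()
    log_norm = logsumexp(joint, axis=1, keepdims=True)
    probs = np.exp(joint - log_norm)
    grid = np.arange(fit.spec.kmax + 1)
    mean = probs @ grid
    mode = grid[np.argmax(probs, axis=1)]
    cdf = np.cumsum(probs, axis=1)
    lower = (cdf < 0.025).sum(axis=1)
    upper = (cdf < 0.975).sum(axis=1)
    return PosteriorAbundance(probs=probs, mean=mean, mode=mode.astype(float),
                              lower=lower.astype(float), upper=upper.astype(float))


@dataclass(frozen=True)
class TotalAbundance:
    """Total abundance across transects with a parametric-bootstrap 95% CI."""

    point: float
    lower: float
    upper: float
    n_boot: int
    n_failed: int


def total_abundance(fit: NMixtureFit, n_boot: int = 1000, seed: int = 0) -> TotalAbundance:
    """Sum of per-site posterior means, with percentile bootstrap interval.

    Each bootstrap replicate simulates counts from the fitted model, refits
    (warm-started at the original optimum), and re-sums the posterior means.
    Replicates whose refit fails are dropped and counted; more than 10%
    failures triggers a warning.
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    point = float(eb_posterior(fit).mean.sum())
    rng = np.random.default_rng(seed)
    draws = []
    failed = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for _ in range(n_boot):
            sim = fit.simulate(rng)
            try:
                refit = fit.refit(sim)
            except (RuntimeError, np.linalg.LinAlgError, ValidationError):
                failed += 1
                continue
            if not refit.converged:
                failed += 1
                continue
            draws.append(float(eb_posterior(refit).mean.sum()))
    if failed > 0.1 * n_boot:
        warnings.warn(f"{failed}/{n_boot} bootstrap refits failed", RuntimeWarning)
    if not draws:
        raise RuntimeError("all bootstrap refits failed")
    lower, upper = np.percentile(draws, [2.5, 97.5])
    return TotalAbundance(point=point, lower=float(lower), upper=float(upper),
                          n_boot=n_boot, n_failed=failed)


def raise_lower_bound(interval, minimum_known_alive: int):
    """Replace an abundance CI's lower bound with a minimum-known-alive count.

    A direct enumeration of distinct individuals (e.g. by ventral-pattern
    photo identification) is a hard lower bound on the population, so the
    statistical lower limit may be raised to it; the upper limit is
    untouched. A minimum above the upper limit is a contradiction.
    """
    lower, upper = float(interval[0]), float(interval[1])
    if minimum_known_alive < 0:
        raise ValidationError("minimum_known_alive must be nonnegative")
    if minimum_known_alive > upper:
        raise ValidationError(
            f"minimum known alive ({minimum_known_alive}) exceeds the interval "
            f"upper bound ({upper})"
        )
    return (max(lower, float(minimum_known_alive)), upper)
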