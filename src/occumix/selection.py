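"""Information-theoretic model selection and parametric-bootstrap fit checks.

Small-sample candidate sets are ranked by AICc, or — when a bootstrap
goodness-of-fit test indicates overdispersion (c-hat > 1) — by the
quasi-likelihood QAICc, in which the deviance is divided by c-hat taken
from the most complex candidate and one extra parameter is charged for
estimating c-hat itself. Goodness of fit uses Pearson's chi-square over
site-visit cells with a parametric-bootstrap null distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ValidationError

__all__ = [
    "aicc",
    "qaicc",
    "rank_models",
    "pearson_chi2",
    "bootstrap_gof",
    "GofResult",
]


def aicc(loglik: float, k_par: int, n_obs: int) -> float:
    """Small-sample Akaike information criterion.

    AICc = -2 LL + 2k + 2k(k+1)/(n - k - 1); the correction term requires
    n > k + 1 and vanishes as n grows, recovering AIC.
    """
    if n_obs <= k_par + 1:
        raise ValidationError(
            f"AICc undefined: n_obs={n_obs} must exceed k_par+1={k_par + 1}"
        )
    return -2.0 * loglik + 2.0 * k_par + 2.0 * k_par * (k_par + 1) / (n_obs - k_par - 1)


def qaicc(loglik: float, k_par: int, n_obs: int, chat: float) -> float:
    """Quasi-likelihood AICc for overdispersed data.

    The deviance is divided by the overdispersion ratio c-hat and one
    parameter is added to ``k_par`` for estimating c-hat, so
    QAICc = -2 LL / c-hat + 2k' + 2k'(k'+1)/(n - k' - 1) with k' = k + 1.
    Estimated c-hat below 1 indicates underdispersion, which the criterion
    cannot exploit; such values are clamped to 1 with a note.
    """
    if chat < 1.0:
        warnings.warn(f"chat={chat:.3f} < 1 clamped to 1", RuntimeWarning)
        chat = 1.0
    k = k_par + 1
    if n_obs <= k + 1:
        raise ValidationError(
            f"QAICc undefined: n_obs={n_obs} must exceed k'+1={k + 1}"
        )
    return -2.0 * loglik / chat + 2.0 * k + 2.0 * k * (k + 1) / (n_obs - k - 1)


def rank_models(fits, n_obs: int, chat: float | None = None, labels=None) -> pd.DataFrame:
    """Rank candidate fits by AICc (or QAICc when ``chat`` is given).

    Fits that failed to converge are excluded (with a warning naming them),
    mirroring the practice of discarding non-converged candidates. The
    returned table is sorted ascending by criterion — ties broken in favour
    of fewer parameters — with delta relative to the best model and Akaike
    weights w_i = exp(-delta_i / 2) / sum_j exp(-delta_j / 2).
    """
    fits = list(fits)
    if labels is None:
        labels = [f"model_{i}" for i in range(len(fits))]
    keep, kept_labels = [], []
    for fit, lab in zip(fits, labels):
        if getattr(fit, "converged", True):
            keep.append(fit)
            kept_labels.append(lab)
        else:
            warnings.warn(f"discarding non-converged model {lab!r}", RuntimeWarning)
    if not keep:
        raise ValidationError("no converged candidate models to rank")

    rows = []
    for fit, lab in zip(keep, kept_labels):
        k = fit.n_params
        if chat is None:
            crit = aicc(fit.loglik, k, n_obs)
            reported_k = k
        else:
            crit = qaicc(fit.loglik, k, n_obs, chat)
            reported_k = k + 1  # the c-hat slot counts as a parameter
        rows.append({"model": lab, "k": reported_k, "loglik": fit.loglik,
                     "criterion": crit})
    table = pd.DataFrame(rows).sort_values(
        ["criterion", "k"], kind="mergesort").reset_index(drop=True)
    table["delta"] = table["criterion"] - table["criterion"].iloc[0]
    w = np.exp(-0.5 * table["delta"].to_numpy())
    table["weight"] = w / w.sum()
    table.attrs["criterion"] = "AICc" if chat is None else "QAICc"
    table.attrs["chat"] = chat
    return table


def pearson_chi2(fit) -> float:
    """Pearson chi-square over observed site-visit cells.

    chi2 = sum (y - yhat)^2 / vhat with the fitted cell mean and variance
    supplied by the model (Bernoulli cells for occupancy, mixture-marginal
    count cells for N-mixture). A zero fitted variance with a nonzero
    residual makes the statistic infinite, which is flagged.
    """
    mean, var, y, mask = fit.expected_cells()
    resid2 = (np.nan_to_num(y) - mean) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        cells = np.where(mask, resid2 / var, 0.0)
    if np.any(~np.isfinite(cells[mask])):
        warnings.warn("zero fitted variance with nonzero residual: "
                      "Pearson statistic is infinite", RuntimeWarning)
        return float("inf")
    return float(cells[mask].sum())


@dataclass(frozen=True)
class GofResult:
    """Parametric-bootstrap goodness-of-fit summary.

    ``p_value`` is the proportion of simulated statistics at least as large
    as the observed one; ``chat`` is observed / bootstrap-mean, the standard
    parametric-bootstrap overdispersion estimator.
    """

    observed: float
    n_sim: int
    boot_mean: float
    p_value: float
    chat: float
    n_failed: int = 0


def bootstrap_gof(fit, n_sim: int = 1000, seed: int = 0) -> GofResult:
    """Simulate from the fitted model, refit, and recompute Pearson chi-square.

    Simulation-refit failures are dropped and counted. The observed
    statistic is referred to the simulated null distribution for the
    p-value; the mean of the null distribution calibrates c-hat.
    """
    if n_sim < 1:
        raise ValidationError("n_sim must be >= 1")
    if not getattr(fit, "converged", True):
        raise ValidationError("goodness of fit requires a converged fit")
    observed = pearson_chi2(fit)
    rng = np.random.default_rng(seed)
    stats = []
    failed = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for _ in range(n_sim):
            sim = fit.simulate(rng)
            try:
                refit = fit.refit(sim)
            except (RuntimeError, np.linalg.LinAlgError, ValidationError):
                failed += 1
                continue
            if not refit.converged:
                failed += 1
                continue
            stats.append(pearson_chi2(refit))
    if not stats:
        raise RuntimeError("all goodness-of-fit refits failed")
    stats = np.asarray(stats)
    boot_mean = float(stats.mean())
    p_value = float(np.mean(stats >= observed))
    return GofResult(observed=observed, n_sim=n_sim, boot_mean=boot_mean,
                     p_value=p_value, chat=observed / boot_mean, n_failed=failed)
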