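"""Synthetic survey-data generator mirroring the study design.

Generates survey frames and observation matrices with the exact statistical
structure the models assume — Bernoulli occupancy states with independent
per-visit detections, or latent count mixtures binomially thinned at each
visit — so that every pipeline stage can be exercised and calibrated
without field data. Defaults emulate the packaged study: 19 site-years,
3-8 visits, cover-object counts and transect lengths resampled with
replacement from the fixture (preserving their skew), four habitat classes.

An optional per-visit availability below 1 injects a controlled closure
violation (temporary emigration): individuals, or an occupied site's
population, are only intermittently available for detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import (
    CountMatrix,
    CovariateSet,
    DetectionHistory,
    HABITATS,
    SurveyDesign,
    ValidationError,
    load_fixture,
)
from .utils import expit

__all__ = [
    "GeneratorConfig",
    "generate_design",
    "simulate_occupancy_data",
    "simulate_counts",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Sampling-frame generator settings; the seed is mandatory.

    ``visits`` is a fixed count or an inclusive (low, high) range;
    ``acos``/``lengths`` are either "fixture" (resample the packaged study
    values with replacement) or explicit pools to resample from.
    """

    seed: int
    n_sites: int = 19
    visits: int | tuple = (3, 8)
    acos: str | tuple = "fixture"
    lengths: str | tuple = "fixture"
    habitats: tuple = HABITATS

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValidationError("n_sites must be >= 1")
        if isinstance(self.visits, tuple):
            lo, hi = self.visits
            if not (1 <= lo <= hi):
                raise ValidationError("visit range must satisfy 1 <= low <= high")
        elif self.visits < 1:
            raise ValidationError("visits must be >= 1")


def generate_design(config: GeneratorConfig) -> tuple[SurveyDesign, CovariateSet]:
    """Draw a reproducible survey frame from the configured pools."""
    rng = np.random.default_rng(config.seed)
    fixture_design, _ = load_fixture()
    aco_pool = (fixture_design.acos if config.acos == "fixture"
                else np.asarray(config.acos, float))
    length_pool = (fixture_design.transect_km if config.lengths == "fixture"
                   else np.asarray(config.lengths, float))
    if np.any(length_pool <= 0):
        raise ValidationError("transect length pool must be positive")
    n = config.n_sites
    if isinstance(config.visits, tuple):
        lo, hi = config.visits
        n_visits = rng.integers(lo, hi + 1, size=n)
    else:
        n_visits = np.full(n, int(config.visits))
    import pandas as pd

    table = pd.DataFrame({
        "site": [f"S{i:03d}" for i in range(n)],
        "year": 2014,
        "habitat": rng.choice(list(config.habitats), size=n),
        "area_ha": np.round(rng.choice(fixture_design.table["area_ha"], size=n), 2),
        "n_visits": n_visits,
        "acos": rng.choice(aco_pool, size=n).astype(int),
        "transect_km": rng.choice(length_pool, size=n),
        "detected": False,
    })
    design = SurveyDesign(table)
    covariates = CovariateSet(
        site=design.table[["habitat", "acos", "transect_km", "area_ha"]].copy()
    )
    return design, covariates


def _per_visit_p(p, shape):
    p = np.asarray(p, float)
    if p.ndim == 0:
        p = np.full(shape, float(p))
    elif p.ndim == 1:
        p = np.broadcast_to(p[:, None], shape).copy()
    if p.shape != shape:
        raise ValidationError(f"detection probability shape {p.shape} != {shape}")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("detection probabilities must lie in [0, 1]")
    return p


def simulate_occupancy_data(
    design: SurveyDesign,
    beta0: float,
    p,
    seed: int,
    length_offset: bool = True,
    availability: float = 1.0,
) -> DetectionHistory:
    """Bernoulli detection histories from the occupancy data model.

    z_i ~ Bernoulli(psi_i) with logit(psi_i) = beta0 (+ ln L_i under the
    offset); y_it | z_i ~ Bernoulli(z_i * p_it) on scheduled visits, missing
    elsewhere. ``availability`` < 1 thins each visit's detection chance,
    emulating temporary emigration.
    """
    if not 0.0 < availability <= 1.0:
        raise ValidationError("availability must be in (0, 1]")
    rng = np.random.default_rng(seed)
    eta = beta0 + (np.log(design.transect_km) if length_offset else 0.0)
    psi = expit(eta)
    shape = (design.n_sites, design.max_visits)
    p = _per_visit_p(p, shape) * availability
    z = rng.random(design.n_sites) < psi
    y = (rng.random(shape) < p) & z[:, None]
    values = np.where(design.visit_mask(), y.astype(float), np.nan)
    return DetectionHistory(values)


def simulate_counts(
    design: SurveyDesign,
    b0: float,
    p,
    seed: int,
    mixture: str = "poisson",
    dispersion: float | None = None,
    zero_inflation: float = 0.0,
    length_offset: bool = True,
    availability: float = 1.0,
) -> CountMatrix:
    """Repeated counts from the N-mixture data model.

    N_i is drawn once per site (closure) from the chosen mixture with mean
    lambda_i = exp(b0 + ln L_i) under the offset; visit counts are binomial
    thinnings y_it ~ Binomial(N_i, p_it). With ``availability`` < 1 each
    visit first draws the available subpopulation Binomial(N_i, availability)
    and detects from it, so counts can exceed no site's true N but closure
    in availability is violated between visits.
    """
    if mixture not in ("poisson", "nb", "zip"):
        raise ValidationError("mixture must be poisson, nb or zip")
    if not 0.0 < availability <= 1.0:
        raise ValidationError("availability must be in (0, 1]")
    if not 0.0 <= zero_inflation < 1.0:
        raise ValidationError("zero_inflation must be in [0, 1)")
    rng = np.random.default_rng(seed)
    lam = np.exp(b0 + (np.log(design.transect_km) if length_offset else 0.0))
    n = design.n_sites
    if mixture == "poisson":
        big_n = rng.poisson(lam)
    elif mixture == "nb":
        if dispersion is None or dispersion <= 0:
            raise ValidationError("negative binomial requires dispersion (size) > 0")
        big_n = rng.negative_binomial(dispersion, dispersion / (dispersion + lam))
    else:
        big_n = np.where(rng.random(n) < zero_inflation, 0, rng.poisson(lam))
    shape = (n, design.max_visits)
    p = _per_visit_p(p, shape)
    if availability < 1.0:
        avail = rng.binomial(big_n[:, None], availability)
        y = rng.binomial(avail, p)
    else:
        y = rng.binomial(big_n[:, None], p)
    values = np.where(design.visit_mask(), y.astype(float), np.nan)
    return CountMatrix(values)
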