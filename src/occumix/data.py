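"""Survey data model, CSV I/O, packaged study fixture, and effort summaries.

The sampling unit throughout is the *site-year*: one transect surveyed
repeatedly within a single season. A :class:`SurveyDesign` is the sampling
frame (visits, artificial cover objects, transect length, habitat), a
:class:`DetectionHistory` / :class:`CountMatrix` holds the site-by-visit
observations with explicit missingness, and a :class:`CovariateSet` carries
site- and visit-level predictors together with the centring/scaling metadata
needed to project new design points onto the model scale.

The packaged fixture transcribes the 19 Jersey grass-snake site-years
(2014-2015): 3-8 visits each, 6-436 cover objects, transect lengths
0.28-19.1 km, four habitat classes. See the fixture CSV header for the two
documented data notes (the visit-count correction and the derivation of the
detected flags).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "HABITATS",
    "SurveyDesign",
    "DetectionHistory",
    "CountMatrix",
    "CovariateSet",
    "EffortSummary",
    "load_survey_table",
    "write_survey_table",
    "load_fixture",
    "fixture_table",
    "build_detection_history",
    "scale_covariates",
    "summarize_effort",
    "apply_removal_design",
]


class SchemaError(ValueError):
    """A file or table is missing required structure (columns, rows)."""


class ValidationError(ValueError):
    """Values are present but violate a domain invariant."""


HABITATS = ("amenity grassland", "dune grassland", "rough grassland", "scrub")

_REQUIRED_COLUMNS = ("site", "year", "habitat", "area_ha", "n_visits", "acos", "transect_km")


@dataclass(frozen=True)
class SurveyDesign:
    """Per-site-year structural record: the sampling frame.

    ``table`` has one row per site-year with columns ``site``, ``year``,
    ``habitat``, ``area_ha``, ``n_visits``, ``acos`` (cover objects checked
    per visit), ``transect_km`` and ``detected`` (naive detection status).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in _REQUIRED_COLUMNS if c not in t.columns]
        if missing:
            raise SchemaError(f"survey table missing columns: {missing}")
        if len(t) == 0:
            raise SchemaError("survey table has no rows")
        if "detected" not in t.columns:
            t = t.assign(detected=False)
        bad = set(t["habitat"]) - set(HABITATS)
        if bad:
            raise ValidationError(f"unknown habitat labels: {sorted(bad)}")
        if (t["n_visits"] < 1).any():
            raise ValidationError("n_visits must be >= 1")
        if (t["transect_km"] <= 0).any():
            raise ValidationError("transect_km must be > 0")
        if (t["area_ha"] <= 0).any():
            raise ValidationError("area_ha must be > 0")
        if (t["acos"] < 0).any():
            raise ValidationError("acos must be >= 0")
        object.__setattr__(self, "table", t.reset_index(drop=True))

    @property
    def n_sites(self) -> int:
        return len(self.table)

    @property
    def labels(self) -> list[str]:
        return [f"{s}{y}" for s, y in zip(self.table["site"], self.table["year"])]

    @property
    def n_visits(self) -> np.ndarray:
        return self.table["n_visits"].to_numpy(int)

    @property
    def max_visits(self) -> int:
        return int(self.n_visits.max())

    @property
    def transect_km(self) -> np.ndarray:
        return self.table["transect_km"].to_numpy(float)

    @property
    def acos(self) -> np.ndarray:
        return self.table["acos"].to_numpy(float)

    @property
    def detected(self) -> np.ndarray:
        return self.table["detected"].to_numpy(bool)

    def visit_mask(self) -> np.ndarray:
        """Boolean (n_sites, max_visits) mask of scheduled visits."""
        return np.arange(self.max_visits)[None, :] < self.n_visits[:, None]


class _VisitMatrix:
    """Rectangular site-by-visit matrix with NaN marking missing visits."""

    def __init__(self, values) -> None:
        arr = np.asarray(values, float)
        if arr.ndim != 2:
            raise ValidationError("expected a 2-D site-by-visit matrix")
        self.values = arr
        self._validate()

    def _validate(self) -> None:  # pragma: no cover - overridden
        raise NotImplementedError

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def max_visits(self) -> int:
        return self.values.shape[1]

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing cells."""
        return ~np.isnan(self.values)

    def __eq__(self, other) -> bool:
        return type(self) is type(other) and np.array_equal(
            self.values, other.values, equal_nan=True
        )

    def __repr__(self) -> str:
        return f"{type(self).__name__}(n_sites={self.n_sites}, max_visits={self.max_visits})"

    def to_frame(self, labels=None) -> pd.DataFrame:
        idx = labels if labels is not None else [str(i) for i in range(self.n_sites)]
        return pd.DataFrame(
            self.values, index=pd.Index(idx, name="site"),
            columns=[f"visit_{t + 1}" for t in range(self.max_visits)],
        )

    def to_csv(self, path, labels=None) -> None:
        # missing visits serialise as empty cells
        self.to_frame(labels).to_csv(path, float_format="%g")

    @classmethod
    def from_csv(cls, path):
        try:
            frame = pd.read_csv(path, index_col=0, comment="#")
        except pd.errors.EmptyDataError as exc:
            raise SchemaError("empty matrix file") from exc
        return cls(frame.to_numpy(float))


class DetectionHistory(_VisitMatrix):
    """Detection/non-detection matrix: entries in {0, 1, missing}."""

    def _validate(self) -> None:
        obs = self.values[~np.isnan(self.values)]
        if not np.all(np.isin(obs, (0.0, 1.0))):
            raise ValidationError("detection history entries must be 0, 1 or missing")

    def any_detection(self) -> np.ndarray:
        """Per-site indicator of at least one detection (missing -> 0)."""
        return np.nansum(self.values, axis=1) > 0


class CountMatrix(_VisitMatrix):
    """Repeated-count matrix: nonnegative integer or missing entries."""

    def _validate(self) -> None:
        obs = self.values[~np.isnan(self.values)]
        if obs.size and (np.any(obs < 0) or np.any(obs != np.round(obs))):
            raise ValidationError("counts must be nonnegative integers or missing")

    def site_max(self) -> np.ndarray:
        with np.errstate(all="ignore"):
            return np.where(self.observed.any(axis=1), np.nanmax(self.values, axis=1), 0.0)


@dataclass(frozen=True)
class CovariateSet:
    """Site- and visit-level covariates plus scaling metadata.

    ``site`` is a one-row-per-site-year table (categorical columns such as
    habitat are kept as strings and dummy-coded by the model modules);
    ``visit`` maps a covariate name to an (n_sites, max_visits) array.
    ``scaling`` records (mean, sd) for every standardised continuous
    covariate so that new design points — "10 cover objects", say — can be
    projected onto the scale the model was trained on.
    """

    site: pd.DataFrame
    visit: dict = field(default_factory=dict)
    scaling: dict = field(default_factory=dict)

    def project(self, name: str, values):
        """Map raw covariate values onto the stored training scale."""
        if name not in self.scaling:
            raise SchemaError(f"no scaling metadata for covariate {name!r}")
        mean, sd = self.scaling[name]
        return (np.asarray(values, float) - mean) / sd

    def unproject(self, name: str, scaled):
        mean, sd = self.scaling[name]
        return np.asarray(scaled, float) * sd + mean


def scale_covariates(covariates: CovariateSet, names=None) -> CovariateSet:
    """Standardise continuous covariates to mean 0, SD 1, recording (mean, sd).

    ``names=None`` scales every numeric site column except structural ones
    (year, visit counts, the detected flag and the transect length, which
    enters models only as an offset) plus every visit-level covariate.
    Quadratic companions (``<name>2``) are added as squares of the scaled
    linear term for any name listed in ``names`` with a trailing ``^2``
    marker, e.g. ``"temperature^2"``.
    """
    site = covariates.site.copy()
    visit = {k: v.copy() for k, v in covariates.visit.items()}
    scaling = dict(covariates.scaling)

    structural = {"year", "n_visits", "n_visits_printed", "detected", "transect_km"}
    if names is None:
        numeric = [
            c for c in site.columns
            if c not in structural and pd.api.types.is_numeric_dtype(site[c])
        ]
        names = numeric + list(visit)
    quad = [n[:-2] for n in names if n.endswith("^2")]
    names = [n for n in names if not n.endswith("^2")]

    for name in list(dict.fromkeys(names + quad)):
        if name in site.columns:
            col = site[name].to_numpy(float)
            mean, sd = float(col.mean()), float(col.std(ddof=1))
            if sd == 0.0 or not np.isfinite(sd):
                raise ValidationError(f"covariate {name!r} has zero variance")
            site[name] = (col - mean) / sd
        elif name in visit:
            arr = visit[name]
            obs = arr[~np.isnan(arr)]
            mean, sd = float(obs.mean()), float(obs.std(ddof=1))
            if sd == 0.0 or not np.isfinite(sd):
                raise ValidationError(f"covariate {name!r} has zero variance")
            visit[name] = (arr - mean) / sd
        else:
            raise SchemaError(f"unknown covariate {name!r}")
        scaling[name] = (mean, sd)
        if name in quad:
            if name in site.columns:
                site[name + "2"] = site[name] ** 2
            else:
                visit[name + "2"] = visit[name] ** 2
    return CovariateSet(site=site, visit=visit, scaling=scaling)


def build_detection_history(counts: CountMatrix) -> DetectionHistory:
    """Threshold counts at >= 1, preserving the missingness pattern."""
    if not isinstance(counts, CountMatrix):
        counts = CountMatrix(counts)
    values = np.where(np.isnan(counts.values), np.nan, (counts.values >= 1).astype(float))
    return DetectionHistory(values)


@dataclass(frozen=True)
class EffortSummary:
    """Descriptive effort totals for a survey design."""

    total_surveys: int
    total_aco_checks: int
    total_km: float
    mean_acos_per_site: float
    mean_transect_km: float
    naive_occupancy: float
    mean_obs_per_survey: float | None = None
    mean_obs_per_transect: float | None = None


def summarize_effort(design: SurveyDesign, counts: CountMatrix | None = None) -> EffortSummary:
    """Total and mean survey effort; observation means when counts are given."""
    k = design.n_visits
    mean_obs_survey = mean_obs_transect = None
    if counts is not None:
        total_obs = float(np.nansum(counts.values))
        n_surveys_observed = int(counts.observed.sum())
        mean_obs_survey = total_obs / n_surveys_observed
        mean_obs_transect = total_obs / design.n_sites
    return EffortSummary(
        total_surveys=int(k.sum()),
        total_aco_checks=int((k * design.acos).sum()),
        total_km=float((k * design.transect_km).sum()),
        mean_acos_per_site=float(design.acos.mean()),
        mean_transect_km=float(design.transect_km.mean()),
        naive_occupancy=float(design.detected.mean()),
        mean_obs_per_survey=mean_obs_survey,
        mean_obs_per_transect=mean_obs_transect,
    )


def apply_removal_design(
    history: DetectionHistory, design: SurveyDesign
) -> tuple[DetectionHistory, EffortSummary]:
    """Truncate each site-year's history after its first detection.

    Under a removal design a site is surveyed only until the species is
    found, so every visit after the first detection is marked missing. The
    returned summary reports the effort actually expended under that rule
    (sites with no detection retain their full schedule).
    """
    values = history.values.copy()
    n, t_max = values.shape
    visits_used = history.observed.sum(axis=1).astype(int)
    for i in range(n):
        hits = np.flatnonzero(values[i] == 1.0)
        if hits.size:
            values[i, hits[0] + 1:] = np.nan
            visits_used[i] = hits[0] + 1
    truncated = DetectionHistory(values)
    detected = truncated.any_detection()
    reduced = SurveyDesign(
        design.table.assign(n_visits=np.maximum(visits_used, 1), detected=detected)
    )
    return truncated, summarize_effort(reduced)


def load_survey_table(path) -> tuple[SurveyDesign, CovariateSet]:
    """Read a one-row-per-site-year CSV into a design and raw covariates.

    Comma-separated, header row, ``#`` comment lines allowed, empty cells
    for missing values. Unknown habitat labels and non-positive transect
    lengths are rejected.
    """
    try:
        table = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty survey table: {path}") from exc
    if "detected" in table.columns:
        table["detected"] = table["detected"].astype(bool)
    design = SurveyDesign(table)
    site_cols = [c for c in ("habitat", "acos", "transect_km", "area_ha") if c in table.columns]
    covariates = CovariateSet(site=design.table[site_cols].copy())
    return design, covariates


def write_survey_table(design: SurveyDesign, path) -> None:
    design.table.to_csv(path, index=False)


def _fixture_path():
    return importlib.resources.files("occumix").joinpath(
        "fixtures/jersey_grass_snakes.csv")


def fixture_table() -> pd.DataFrame:
    """Full packaged fixture, including the published per-transect estimates."""
    with importlib.resources.as_file(_fixture_path()) as p:
        return pd.read_csv(p, comment="#")


def load_fixture() -> tuple[SurveyDesign, CovariateSet]:
    """The 19 Jersey grass-snake site-years as a design + raw covariates."""
    with importlib.resources.as_file(_fixture_path()) as p:
        return load_survey_table(p)
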