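"""Design-matrix construction shared by the occupancy and N-mixture models.

Covariates named in a model specification are resolved against a
:class:`~occumix.data.CovariateSet`: numeric site columns enter as single
columns (assumed already standardised by ``scale_covariates``), categorical
site columns are dummy-coded against a reference level (first level in
sorted order), and visit-level covariates come from the set's visit arrays,
with site columns broadcast across visits when a detection covariate is
site-level (e.g. cover objects counted once per site-year).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CovariateSet, SchemaError


@dataclass(frozen=True)
class Term:
    name: str
    kind: str  # "num" or "cat"
    levels: tuple = ()
    visit_level: bool = False

    @property
    def columns(self) -> list[str]:
        if self.kind == "num":
            return [self.name]
        return [f"{self.name}[{lv}]" for lv in self.levels[1:]]

    @property
    def width(self) -> int:
        return 1 if self.kind == "num" else len(self.levels) - 1


def resolve_terms(covariates: CovariateSet, names) -> list[Term]:
    terms = []
    for name in names:
        if name in covariates.visit:
            terms.append(Term(name, "num", visit_level=True))
        elif name in covariates.site.columns:
            col = covariates.site[name]
            if pd.api.types.is_numeric_dtype(col):
                terms.append(Term(name, "num"))
            else:
                levels = tuple(sorted(col.astype(str).unique()))
                if len(levels) < 2:
                    raise SchemaError(f"categorical covariate {name!r} has one level")
                terms.append(Term(name, "cat", levels=levels))
        else:
            raise SchemaError(f"unknown covariate {name!r}")
    return terms


def n_coefficients(terms) -> int:
    return 1 + sum(t.width for t in terms)


def column_names(terms, intercept="(intercept)") -> list[str]:
    out = [intercept]
    for t in terms:
        out.extend(t.columns)
    return out


def _term_site_columns(covariates, term, n):
    if term.kind == "num":
        return covariates.site[term.name].to_numpy(float).reshape(n, 1)
    col = covariates.site[term.name].astype(str).to_numpy()
    return np.column_stack([(col == lv).astype(float) for lv in term.levels[1:]])


def site_matrix(covariates: CovariateSet, terms, n_sites: int) -> np.ndarray:
    """(n_sites, 1 + k) matrix with a leading intercept column."""
    blocks = [np.ones((n_sites, 1))]
    for t in terms:
        if t.visit_level:
            raise SchemaError(f"visit-level covariate {t.name!r} on a site-level parameter")
        blocks.append(_term_site_columns(covariates, t, n_sites))
    return np.concatenate(blocks, axis=1)


def visit_matrix(covariates: CovariateSet, terms, shape) -> np.ndarray:
    """(n_sites, max_visits, 1 + k) matrix; site-level terms broadcast over visits."""
    n, t_max = shape
    blocks = [np.ones((n, t_max, 1))]
    for t in terms:
        if t.visit_level:
            arr = covariates.visit[t.name]
            if arr.shape != (n, t_max):
                raise SchemaError(
                    f"visit covariate {t.name!r} has shape {arr.shape}, expected {(n, t_max)}"
                )
            blocks.append(np.nan_to_num(arr)[:, :, None])
        else:
            cols = _term_site_columns(covariates, t, n)
            blocks.append(np.broadcast_to(cols[:, None, :], (n, t_max, cols.shape[1])))
    return np.concatenate(blocks, axis=2)


def prediction_row(terms, values: dict, covariates: CovariateSet) -> np.ndarray:
    """Intercept-plus-covariates row for a new design point.

    Numeric values are given in raw units and projected onto the training
    scale when scaling metadata exists; categorical values are labels.
    """
    row = [1.0]
    for t in terms:
        if t.name not in values:
            raise SchemaError(f"no value supplied for covariate {t.name!r}")
        v = values[t.name]
        if t.kind == "num":
            if t.name in covariates.scaling:
                v = float(covariates.project(t.name, v))
            row.append(float(v))
        else:
            if str(v) not in t.levels:
                raise SchemaError(f"unknown level {v!r} for covariate {t.name!r}")
            row.extend(float(str(v) == lv) for lv in t.levels[1:])
    return np.asarray(row)
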