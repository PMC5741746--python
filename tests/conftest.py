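import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import occumix as ox

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixture_bundle():
    """Packaged 19-site-year study design with raw covariates."""
    return ox.load_fixture()


@pytest.fixture(scope="session")
def fixture_design(fixture_bundle):
    return fixture_bundle[0]


@pytest.fixture(scope="session")
def fixture_covariates(fixture_bundle):
    return fixture_bundle[1]


@pytest.fixture(scope="session")
def fixture_estimates():
    """Published per-transect estimate columns from the fixture."""
    return ox.fixture_table()


@pytest.fixture()
def no_covariates():
    """Single-site covariate set for offset-free constant models."""
    def make(n_sites, transect_km=None):
        site = pd.DataFrame(index=range(n_sites))
        if transect_km is not None:
            site["transect_km"] = np.asarray(transect_km, float)
        return ox.CovariateSet(site=site)
    return make


@pytest.fixture(scope="session")
def aco_fit():
    """Occupancy fit with a detection-effort (cover object) covariate on a
    large synthetic dataset: the shared input for effort/power planners."""
    cfg = ox.GeneratorConfig(seed=42, n_sites=400)
    design, raw = ox.generate_design(cfg)
    covs = ox.scale_covariates(raw, names=["acos"])
    aco_scaled = covs.site["acos"].to_numpy()
    p_site = 1.0 / (1.0 + np.exp(-(-0.7 + 0.8 * aco_scaled)))
    hist = ox.simulate_occupancy_data(design, beta0=float(np.log(0.44 / 0.56)),
                                      p=p_site, seed=43)
    spec = ox.OccupancyModelSpec(detection=("acos",))
    return ox.fit_occupancy(hist, covs, spec, seed=0)
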