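"""N-mixture likelihood, mixtures, empirical-Bayes abundance, bootstrap CI."""

import numpy as np
import pytest

import occumix as ox
from occumix.utils import expit

from _oracles import posterior_table, sum_nmixture_nll

B_KM = float(np.log(0.44))  # log abundance per km


class TestNegLogLik:
    def test_empty_population_limit(self, no_covariates):
        counts = ox.CountMatrix([[0.0]])
        spec = ox.NMixtureModelSpec(length_offset=False, fixed_detection=0.5)
        nll = ox.nmixture_negloglik([-50.0], counts, no_covariates(1), spec)
        assert nll == pytest.approx(0.0, abs=1e-10)

    def test_matches_direct_summation(self, no_covariates):
        y = np.array([[1.0, 0.0], [2.0, 1.0]])
        counts = ox.CountMatrix(y)
        spec = ox.NMixtureModelSpec(length_offset=False, kmax=6)
        nll = ox.nmixture_negloglik([0.0, 0.0], counts, no_covariates(2), spec)
        oracle = sum_nmixture_nll([1.0, 1.0], np.full((2, 2), 0.5), y, kmax=6)
        assert nll == pytest.approx(oracle, abs=1e-10)

    @pytest.mark.parametrize("mixture, extra, kwargs", [
        ("nb", np.log(2.0), {"prior": "nb", "size": 2.0}),
        ("zip", 0.0, {"prior": "zip", "pi": 0.5}),
    ])
    def test_mixture_variants_match_summation(self, mixture, extra, kwargs,
                                              no_covariates):
        y = np.array([[0.0, 1.0], [3.0, np.nan]])
        counts = ox.CountMatrix(y)
        spec = ox.NMixtureModelSpec(mixture=mixture, length_offset=False, kmax=12)
        nll = ox.nmixture_negloglik([0.2, 0.4, extra], counts, no_covariates(2), spec)
        lam = [np.exp(0.4)] * 2
        p = np.full((2, 2), expit(0.2))
        assert nll == pytest.approx(
            sum_nmixture_nll(lam, p, y, kmax=12, **kwargs), abs=1e-10)

    def test_count_above_kmax_rejected(self, no_covariates):
        counts = ox.CountMatrix([[7.0]])
        spec = ox.NMixtureModelSpec(length_offset=False, kmax=5)
        with pytest.raises(ox.ValidationError):
            ox.nmixture_negloglik([0.0, 0.0], counts, no_covariates(1), spec)

    def test_truncation_bound_sufficient_at_study_scale(self, fixture_design,
                                                        fixture_covariates):
        counts = ox.simulate_counts(fixture_design, B_KM, 0.33, seed=31)
        spec50 = ox.NMixtureModelSpec(kmax=50)
        spec100 = ox.NMixtureModelSpec(kmax=100)
        params = [-0.7, B_KM]
        a = ox.nmixture_negloglik(params, counts, fixture_covariates, spec50)
        b = ox.nmixture_negloglik(params, counts, fixture_covariates, spec100)
        assert abs(a - b) < 1e-6

    def test_nb_limit_is_poisson(self, no_covariates):
        counts = ox.CountMatrix([[1.0, 0.0], [2.0, 2.0]])
        covs = no_covariates(2)
        pois = ox.nmixture_negloglik(
            [0.0, 0.3], counts, covs, ox.NMixtureModelSpec(length_offset=False))
        nb = ox.nmixture_negloglik(
            [0.0, 0.3, np.log(1e8)], counts, covs,
            ox.NMixtureModelSpec(mixture="nb", length_offset=False))
        assert nb == pytest.approx(pois, abs=1e-4)

    def test_zip_with_zero_inflation_zero_is_poisson(self, no_covariates):
        counts = ox.CountMatrix([[1.0, 0.0], [2.0, 2.0]])
        covs = no_covariates(2)
        pois = ox.nmixture_negloglik(
            [0.0, 0.3], counts, covs, ox.NMixtureModelSpec(length_offset=False))
        zip_ = ox.nmixture_negloglik(
            [0.0, 0.3, -700.0], counts, covs,
            ox.NMixtureModelSpec(mixture="zip", length_offset=False))
        assert zip_ == pytest.approx(pois, abs=1e-12)


class TestFit:
    def test_parameter_counts(self, fixture_design, fixture_covariates):
        counts = ox.simulate_counts(fixture_design, B_KM, 0.33, seed=33)
        pois = ox.fit_nmixture(counts, fixture_covariates,
                               ox.NMixtureModelSpec(), seed=0)
        assert pois.n_params == 2
        nb = ox.fit_nmixture(counts, fixture_covariates,
                             ox.NMixtureModelSpec(mixture="nb"), seed=0)
        assert nb.n_params == 3

    def test_perfect_detection_single_visit_closed_form(self, no_covariates):
        rng = np.random.default_rng(2)
        y = rng.poisson(3.0, size=(60, 1)).astype(float)
        counts = ox.CountMatrix(y)
        spec = ox.NMixtureModelSpec(length_offset=False, fixed_detection=1.0,
                                    kmax=30)
        fit = ox.fit_nmixture(counts, no_covariates(60), spec, seed=0)
        # with p = 1 and one visit the Poisson MLE is the sample mean
        assert np.exp(fit.ab_coefs[0]) == pytest.approx(y.mean(), abs=1e-5)

    def test_recovers_generating_intercept(self):
        cfg = ox.GeneratorConfig(seed=11, n_sites=500, visits=8)
        design, covs = ox.generate_design(cfg)
        counts = ox.simulate_counts(design, B_KM, 0.33, seed=11)
        fit = ox.fit_nmixture(counts, covs, ox.NMixtureModelSpec(), seed=0)
        se = np.sqrt(fit.vcov[1, 1])
        assert fit.converged
        assert abs(fit.ab_coefs[0] - B_KM) < 3 * se

    def test_per_km_intercept_invariant_to_length_rescaling(self):
        """Doubling every transect length (offset on) should leave the per-km
        abundance intercept unchanged up to sampling error."""
        design, covs = ox.generate_design(ox.GeneratorConfig(seed=17, n_sites=600,
                                                             visits=6))
        doubled_table = design.table.assign(
            transect_km=design.table["transect_km"] * 2)
        design2 = ox.SurveyDesign(doubled_table)
        covs2 = ox.CovariateSet(site=design2.table[covs.site.columns].copy())
        spec = ox.NMixtureModelSpec()
        fits = []
        for d, c, seed in ((design, covs, 71), (design2, covs2, 72)):
            counts = ox.simulate_counts(d, B_KM, 0.4, seed=seed)
            fits.append(ox.fit_nmixture(counts, c, spec, seed=0))
        se = np.hypot(np.sqrt(fits[0].vcov[1, 1]), np.sqrt(fits[1].vcov[1, 1]))
        assert abs(fits[0].ab_coefs[0] - fits[1].ab_coefs[0]) < 3 * se


class TestPosterior:
    def test_tiny_lambda_concentrates_at_zero(self, no_covariates):
        counts = ox.CountMatrix([[0.0, 0.0]])
        spec = ox.NMixtureModelSpec(length_offset=False, fixed_detection=0.5)
        fit = ox.fit_nmixture(counts, no_covariates(1), spec, seed=0,
                              hessian=False)
        post = ox.eb_posterior(fit)
        assert post.probs[0, 0] > 0.999
        assert post.mean[0] < 0.01

    def test_perfect_detection_degenerate(self, no_covariates):
        counts = ox.CountMatrix([[2.0]])
        spec = ox.NMixtureModelSpec(length_offset=False, fixed_detection=1.0,
                                    kmax=10)
        fit = ox.fit_nmixture(counts, no_covariates(1), spec, seed=0,
                              hessian=False)
        post = ox.eb_posterior(fit)
        assert post.probs[0, 2] == pytest.approx(1.0, abs=1e-12)
        assert post.mean[0] == pytest.approx(2.0, abs=1e-12)
        assert (post.lower[0], post.upper[0]) == (2, 2)

    def test_matches_hand_normalised_bayes_table(self, no_covariates):
        """lambda=1, p=0.5, y=[1, 0], Kmax=10 against an explicitly
        normalised prior-times-likelihood table."""
        from occumix.nmixture import _site_loglik_matrix  # noqa: F401
        counts = ox.CountMatrix([[1.0, 0.0]])
        spec = ox.NMixtureModelSpec(length_offset=False, fixed_detection=0.5,
                                    kmax=10)
        fit = ox.fit_nmixture(counts, no_covariates(1), spec, seed=0,
                              hessian=False)
        fit.params = np.array([0.0])  # pin lambda at exp(0) = 1
        post = ox.eb_posterior(fit)
        oracle = posterior_table(1.0, 0.5, [1, 0], 10)
        np.testing.assert_allclose(post.probs[0], oracle, atol=1e-12)

    def test_posterior_invariants(self, fixture_design, fixture_covariates):
        counts = ox.simulate_counts(fixture_design, B_KM, 0.4, seed=41)
        fit = ox.fit_nmixture(counts, fixture_covariates,
                              ox.NMixtureModelSpec(), seed=0)
        post = ox.eb_posterior(fit)
        np.testing.assert_allclose(post.probs.sum(axis=1), 1.0, atol=1e-9)
        site_max = counts.site_max()
        grid = np.arange(fit.spec.kmax + 1)
        below = grid[None, :] < site_max[:, None]
        assert post.probs[below].max(initial=0.0) == 0.0
        assert np.all(post.mean >= site_max - 1e-9)


class TestTotalAbundance:
    def test_perfect_detection_single_visit_equals_observed_sum(self,
                                                                no_covariates):
        rng = np.random.default_rng(5)
        y = rng.poisson(2.0, size=(25, 1)).astype(float)
        counts = ox.CountMatrix(y)
        spec = ox.NMixtureModelSpec(length_offset=False, fixed_detection=1.0,
                                    kmax=20)
        fit = ox.fit_nmixture(counts, no_covariates(25), spec, seed=0)
        total = ox.total_abundance(fit, n_boot=20, seed=1)
        assert total.point == pytest.approx(y.sum(), abs=1e-6)

    def test_bootstrap_interval_brackets_point(self, fixture_design,
                                               fixture_covariates):
        counts = ox.simulate_counts(fixture_design, B_KM, 0.4, seed=47)
        fit = ox.fit_nmixture(counts, fixture_covariates,
                              ox.NMixtureModelSpec(), seed=0)
        total = ox.total_abundance(fit, n_boot=60, seed=2)
        assert total.lower <= total.upper
        assert total.n_failed <= 6

    def test_bootstrap_interval_covers_generating_total(self, fixture_design,
                                                        fixture_covariates):
        """At the study scale the 95% bootstrap CI should cover the
        generating expected total in most replicates (binomial 95% bound at
        20 replicates for a true rate of 0.95 allows down to 15 hits)."""
        expected_total = 0.44 * fixture_design.transect_km.sum()
        spec = ox.NMixtureModelSpec()
        hits = 0
        for rep in range(20):
            counts = ox.simulate_counts(fixture_design, B_KM, 0.4,
                                        seed=900 + rep)
            try:
                fit = ox.fit_nmixture(counts, fixture_covariates, spec, seed=0,
                                      hessian=False)
                total = ox.total_abundance(fit, n_boot=40, seed=rep)
            except RuntimeError:
                hits += 1  # count a failed replicate as neutral, not a miss
                continue
            if total.lower <= expected_total <= total.upper:
                hits += 1
        assert hits >= 15


class TestRaiseLowerBound:
    def test_raises_to_minimum_known_alive(self):
        assert ox.raise_lower_bound((20, 169), 43) == (43, 169)

    def test_noop_when_minimum_below_lower(self):
        assert ox.raise_lower_bound((20, 169), 10) == (20, 169)

    def test_contradiction_rejected(self):
        with pytest.raises(ox.ValidationError):
            ox.raise_lower_bound((20, 169), 200)
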