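"""Independent brute-force oracles used across the test suite.

Everything here is written in deliberately plain, slow style (explicit
loops, itertools enumeration, scalar arithmetic) and shares no code with
the package's vectorised likelihoods, so agreement is meaningful.
"""

import itertools
import math

import numpy as np
from scipy.optimize import minimize
from scipy.special import comb
from scipy.stats import binom as binom_dist, poisson as poisson_dist


def enum_occupancy_nll(psi, p, y):
    """Occupancy NLL by exhaustive enumeration over all 2^n occupancy-state
    combinations. psi: (n,), p: (n, T), y: (n, T) with NaN missing."""
    n = len(psi)
    total = 0.0
    for i in range(n):
        site_prob = 0.0
        for z in (0, 1):
            prob = psi[i] if z == 1 else 1.0 - psi[i]
            for t in range(y.shape[1]):
                if math.isnan(y[i][t]):
                    continue
                if z == 1:
                    prob *= p[i][t] if y[i][t] == 1 else 1.0 - p[i][t]
                else:
                    prob *= 1.0 if y[i][t] == 0 else 0.0
            site_prob += prob
        total += math.log(site_prob)
    return -total


def enum_occupancy_nll_joint(psi, p, y):
    """Same likelihood via literal enumeration of joint z-vectors (2^n terms),
    confirming the per-site factorisation used above."""
    n = len(psi)
    total_ll = 0.0
    # joint probability of the full dataset = sum over z in {0,1}^n
    joint = 0.0
    for zvec in itertools.product((0, 1), repeat=n):
        prob = 1.0
        for i, z in enumerate(zvec):
            prob *= psi[i] if z else 1.0 - psi[i]
            for t in range(y.shape[1]):
                if math.isnan(y[i][t]):
                    continue
                if z:
                    prob *= p[i][t] if y[i][t] == 1 else 1.0 - p[i][t]
                elif y[i][t] == 1:
                    prob = 0.0
        joint += prob
    total_ll = math.log(joint)
    return -total_ll


def sum_nmixture_nll(lam, p, y, kmax, prior="poisson", size=None, pi=0.0):
    """N-mixture NLL by direct summation over N = 0..kmax per site."""
    n = len(lam)
    total = 0.0
    for i in range(n):
        site_prob = 0.0
        for big_n in range(kmax + 1):
            if prior == "poisson":
                f = poisson_dist.pmf(big_n, lam[i])
            elif prior == "nb":
                from scipy.stats import nbinom
                f = nbinom.pmf(big_n, size, size / (size + lam[i]))
            else:
                f = pi * (big_n == 0) + (1 - pi) * poisson_dist.pmf(big_n, lam[i])
            prob = f
            for t in range(y.shape[1]):
                if math.isnan(y[i][t]):
                    continue
                prob *= binom_dist.pmf(y[i][t], big_n, p[i][t])
            site_prob += prob
        total += math.log(site_prob)
    return -total


def posterior_table(lam, p, y_row, kmax):
    """Hand-normalised empirical-Bayes posterior for one site."""
    weights = []
    for big_n in range(kmax + 1):
        w = poisson_dist.pmf(big_n, lam)
        for t, y in enumerate(y_row):
            w *= binom_dist.pmf(y, big_n, p)
        weights.append(w)
    total = sum(weights)
    return [w / total for w in weights]


def constant_occupancy_mle(det_counts, k):
    """MLE of (psi, p) for a constant-constant occupancy model from the
    per-site detection counts d_i out of k visits (sufficient statistics)."""
    values, counts = np.unique(det_counts, return_counts=True)

    def nll(theta):
        psi = 1.0 / (1.0 + np.exp(-theta[0]))
        p = 1.0 / (1.0 + np.exp(-theta[1]))
        ll = 0.0
        for d, m in zip(values, counts):
            lik = psi * comb(k, d) * p**d * (1 - p) ** (k - d)
            if d == 0:
                lik += 1.0 - psi
            ll += m * np.log(max(lik, 1e-300))
        return -ll

    res = minimize(nll, [0.0, 0.0], method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-9})
    return 1.0 / (1.0 + np.exp(-res.x[0])), 1.0 / (1.0 + np.exp(-res.x[1]))


def simulated_power(psi1, psi2, p, k, n_sites, alpha, n_reps, rng, variance_factor):
    """Empirical power of the one-tailed two-period z-test at n_sites per
    period, with plug-in variance factors evaluated at the MLEs."""
    from scipy.stats import norm

    z_crit = norm.ppf(1.0 - alpha)
    rejections = 0
    usable = 0
    for _ in range(n_reps):
        est = []
        ok = True
        for psi in (psi1, psi2):
            z = rng.random(n_sites) < psi
            d = rng.binomial(k, p, size=n_sites) * z
            psi_hat, p_hat = constant_occupancy_mle(d, k)
            if not (1e-4 < psi_hat < 1 - 1e-4 and 1e-4 < p_hat < 1 - 1e-4):
                ok = False
                break
            try:
                v = variance_factor(psi_hat, p_hat, k)
            except Exception:
                ok = False
                break
            est.append((psi_hat, v))
        if not ok:
            continue
        usable += 1
        (e1, v1), (e2, v2) = est
        z_stat = (e1 - e2) / math.sqrt((v1 + v2) / n_sites)
        if z_stat > z_crit:
            rejections += 1
    return rejections / max(usable, 1)


def brute_force_sites(psi1, psi2, p, k, alpha, target_power, rng, variance_factor,
                      s_grid, n_reps=300):
    """Smallest candidate site number whose simulated power reaches the target."""
    for s in s_grid:
        power = simulated_power(psi1, psi2, p, k, s, alpha, n_reps, rng,
                                variance_factor)
        if power >= target_power:
            return s
    return None
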