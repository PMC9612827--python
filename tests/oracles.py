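"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's sampling code: posterior inclusion
probabilities are computed by exhaustive enumeration of all 2^m inclusion
configurations with closed-form Gaussian marginal likelihoods.
"""

import itertools

import numpy as np
from scipy.special import logsumexp


def exact_pips(y, H, pi, d0, d1, sigma2):
    """Exact PIPs by enumerating all 2^m spike/slab configurations.

    Model: y ~ N(0, sigma2 I + H D H') with D_jj = d1 if gamma_j = 1 else
    d0, and independent Bernoulli(pi) priors on gamma_j.
    """
    y = np.asarray(y, float)
    H = np.asarray(H, float)
    n, m = H.shape
    G = H.T @ H
    Hty = H.T @ y
    yty = float(y @ y)
    log_prior_1 = np.log(pi)
    log_prior_0 = np.log1p(-pi)
    logps = []
    configs = list(itertools.product([0, 1], repeat=m))
    for gamma in configs:
        g = np.array(gamma)
        D = np.where(g == 1, d1, d0)
        # Woodbury: Sigma = s2 I + H D H'
        M = np.diag(1.0 / D) + G / sigma2
        sign, logdet_M = np.linalg.slogdet(M)
        assert sign > 0
        logdet = n * np.log(sigma2) + np.log(D).sum() + logdet_M
        quad = yty / sigma2 - (Hty / sigma2) @ np.linalg.solve(M, Hty / sigma2)
        loglik = -0.5 * (n * np.log(2 * np.pi) + logdet + quad)
        logps.append(loglik + g.sum() * log_prior_1
                     + (m - g.sum()) * log_prior_0)
    logps = np.array(logps)
    logps -= logsumexp(logps)
    post = np.exp(logps)
    pips = np.zeros(m)
    for prob, gamma in zip(post, configs):
        pips += prob * np.array(gamma)
    return pips


def direct_gaussian_logpdf(y, cov):
    """Dense reference log-density used to validate the Woodbury identity."""
    from scipy.stats import multivariate_normal

    return multivariate_normal(mean=np.zeros(len(y)), cov=cov).logpdf(y)
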