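"""Numba kernel for the per-coefficient collapsed spike-and-slab sweep.

The kernel mutates the residual, effect, and inclusion vectors in place.
All random numbers are drawn outside (from the run's single numpy
Generator) and passed in, so results are bit-reproducible for a given seed
and independent of numba's internal RNG.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True, fastmath=False)
def sweep_coefficients(Ht, col_ss, r, beta, gamma, logit_pi,
                       d0, d1, sig2, order, u_unif, z_norm):
    """One systematic-scan sweep over all coefficients in the given order.

    Ht : (m, n) transposed design, rows contiguous.
    col_ss : (m,) column sums of squares h_j'h_j.
    r : (n,) current residual y - C a - H b, updated in place.
    beta, gamma : (m,) current effects / inclusion indicators, in place.
    logit_pi : (m,) per-coefficient prior log-odds of inclusion.
    d0, d1 : spike and slab variances; sig2 : residual variance.
    order : (m,) visit order; u_unif, z_norm : (m,) random draws.
    """
    m, n = Ht.shape
    flips = 0
    for t in range(m):
        j = order[t]
        hj = Ht[j]
        bj = beta[j]
        v = col_ss[j]
        u = col_ss[j] * bj
        for i in range(n):
            u += hj[i] * r[i]
        # log marginal-likelihood ratio, slab vs spike, beta_j integrated out
        s1 = sig2 + d1 * v
        s0 = sig2 + d0 * v
        llr = -0.5 * (math.log(s1) - math.log(s0)) \
            + 0.5 * (u * u / sig2) * (d1 / s1 - d0 / s0)
        logit = logit_pi[j] + llr
        if logit > 35.0:
            p1 = 1.0
        elif logit < -35.0:
            p1 = 0.0
        else:
            p1 = 1.0 / (1.0 + math.exp(-logit))
        g_new = 1 if u_unif[t] < p1 else 0
        if g_new != gamma[j]:
            flips += 1
        gamma[j] = g_new
        d = d1 if g_new == 1 else d0
        post_var = 1.0 / (v / sig2 + 1.0 / d)
        post_mean = post_var * u / sig2
        b_new = post_mean + math.sqrt(post_var) * z_norm[t]
        diff = bj - b_new
        if diff != 0.0:
            for i in range(n):
                r[i] += hj[i] * diff
        beta[j] = b_new
    return flips


@njit(cache=True)
def residual_sumsq(r):
    s = 0.0
    for i in range(r.shape[0]):
        s += r[i] * r[i]
    return s
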