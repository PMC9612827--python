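"""Genome-wide Bayesian spike-and-slab haplotype fine-mapping.

Model:  y = C a + H b + e,  with a spike-and-slab prior on each
haplotype-cluster effect b_i:

    b_i | g_i ~ N(0, d0^2) if g_i = 0  else  N(0, d1^2),
    g_i ~ Bernoulli(pi_i),   d1^{-2} ~ Gamma(a, b),

where d0^2 is fixed close to zero.  Inference is by Gibbs sampling with the
inclusion indicator updated from the collapsed (effect-integrated) marginal
likelihood ratio.  The per-block posterior inclusion probability (PIP) is
the posterior frequency of the event that any of the block's clusters is in
the slab.  The inclusion prior pi can be fixed, given a Beta hyperprior
shared across blocks, or driven by block-level annotations through a probit
link Phi^{-1}(pi_B) = A_B' theta inferred by truncated-normal data
augmentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.special import ndtr, ndtri
from sklearn.base import BaseEstimator

from ._gibbs import sweep_coefficients

logger = logging.getLogger("hapfm")

_EPS = 1e-12


@dataclass
class SpikeSlabPrior:
    """Hyperparameters of the spike-and-slab hierarchy.

    delta0_sq : spike variance (fixed, near zero).
    a, b : shape/rate of the Gamma prior on the slab precision d1^{-2}.
    pi : fixed inclusion prior; None activates the Beta(a_pi, b_pi)
        hyperprior (or the annotation probit model when annotations are
        supplied).
    a_e, b_e : shape/rate of the Gamma prior on the residual precision.
    tau_sq : prior variance of the annotation effects theta.
    """

    delta0_sq: float = 1e-4
    a: float = 0.1
    b: float = 0.1
    pi: float | None = None
    a_pi: float = 1.0
    b_pi: float = 99.0
    a_e: float = 0.01
    b_e: float = 0.01
    tau_sq: float = 1.0

    def __post_init__(self) -> None:
        if self.delta0_sq <= 0 or self.a <= 0 or self.b <= 0:
            raise ValueError("delta0_sq, a, b must be positive")
        if self.pi is not None and not (0 < self.pi < 1):
            raise ValueError("fixed pi must lie in (0, 1)")


@dataclass
class PosteriorSummary:
    """Posterior summaries of one fine-mapping run."""

    block_pip: np.ndarray
    cluster_pip: np.ndarray
    beta_mean: np.ndarray
    beta_sd: np.ndarray
    alpha_mean: np.ndarray | None
    alpha_sd: np.ndarray | None
    sigma2_mean: float
    delta1_sq_mean: float
    pi_mean: float | None
    theta_mean: np.ndarray | None
    theta_sd: np.ndarray | None
    block_of: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def block_effect_size(self) -> np.ndarray:
        """Largest absolute posterior-mean cluster effect within each block."""
        n_blocks = len(self.block_pip)
        out = np.zeros(n_blocks)
        for k in range(n_blocks):
            cols = np.where(self.block_of == k)[0]
            if cols.size:
                out[k] = np.abs(self.beta_mean[cols]).max()
        return out


def _ess(x: np.ndarray) -> float:
    """Effective sample size from the initial positive autocorrelation sum."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or x.std() == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (xc @ xc)
    s = 0.0
    for k in range(1, n // 2):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(n / (1 + 2 * s))


def probit_prior_step(block_gamma: np.ndarray, A: np.ndarray,
                      theta: np.ndarray, tau_sq: float,
                      rng: np.random.Generator,
                      prior_mean: np.ndarray | None = None):
    """One data-augmentation update of the probit annotation model.

    Given current block inclusion indicators, draws latent truncated
    normals z_B ~ N(A_B' theta, 1) restricted to (0, inf) for included
    blocks and (-inf, 0] otherwise, then theta from its Gaussian
    conditional under the N(prior_mean, tau_sq I) prior (zero mean by
    default).  Returns ``(theta_new, z, pi_block)`` with
    ``pi_block = Phi(A theta_new)``.
    """
    mu = A @ theta
    u = rng.random(len(mu))
    p0 = np.clip(ndtr(-mu), _EPS, 1 - _EPS)  # P(z < 0 | mu)
    arg = np.where(block_gamma > 0, p0 + u * (1 - p0), u * p0)
    z = mu + ndtri(np.clip(arg, _EPS, 1 - _EPS))
    k = A.shape[1]
    m0 = np.zeros(k) if prior_mean is None else np.asarray(prior_mean, float)
    prec = A.T @ A + np.eye(k) / tau_sq
    cf = cho_factor(prec)
    mean = cho_solve(cf, A.T @ z + m0 / tau_sq)
    L = cholesky(prec, lower=False)
    theta_new = mean + solve_triangular(L, rng.standard_normal(k))
    pi_block = np.clip(ndtr(A @ theta_new), 1e-6, 1 - 1e-6)
    return theta_new, z, pi_block


def select_significant(pips: np.ndarray, q: float = 0.05):
    """Bayesian FDR selection on PIPs.

    Blocks are ranked by PIP (descending, ties by block order); the
    significant set is the largest prefix whose mean (1 - PIP) is at most
    ``q``.  Returns ``(selected, running_fdr)`` where ``selected`` lists the
    chosen block indices in rank order and ``running_fdr[k]`` is the
    achieved Bayesian FDR of the prefix ending at block ``k``.
    """
    pips = np.asarray(pips, dtype=float)
    if np.any((pips < 0) | (pips > 1)):
        raise ValueError("PIPs must lie in [0, 1]")
    order = np.argsort(-pips, kind="stable")
    cum = np.cumsum(1.0 - pips[order]) / np.arange(1, len(pips) + 1)
    k_sel = np.nonzero(cum <= q)[0]
    selected = [int(b) for b in order[: k_sel[-1] + 1]] if k_sel.size else []
    running = np.empty_like(cum)
    running[order] = cum
    return selected, running


class SpikeSlabFineMapper(BaseEstimator):
    """Spike-and-slab Gibbs fine-mapper with a scikit-learn interface.

    Parameters
    ----------
    n_iter, burn_in, thin : int
        Gibbs schedule; post-burn-in draws are retained every ``thin``
        sweeps.
    delta0_sq, a_slab, b_slab, pi, a_pi, b_pi, a_e, b_e, tau_sq : float
        Prior hyperparameters (see :class:`SpikeSlabPrior`).
    fixed_delta1_sq, fixed_sigma_sq : float, optional
        Freeze the slab or residual variance (used for oracle checks).
    group_gamma : bool, default False
        Sample one inclusion indicator per block (scaling all member
        cluster effects) instead of one per cluster.
    random_state : int or numpy Generator, optional

    Attributes
    ----------
    pip_ : ndarray, shape (n_blocks,)
        Per-block posterior inclusion probability.
    cluster_pip_, beta_mean_, beta_sd_ : ndarray, shape (m,)
    alpha_mean_ : ndarray or None
        Posterior mean covariate effects.
    summary_ : PosteriorSummary
    """

    def __init__(self, n_iter: int = 20_000, burn_in: int = 5_000,
                 thin: int = 5, delta0_sq: float = 1e-4, a_slab: float = 0.1,
                 b_slab: float = 0.1, pi: float | None = None,
                 a_pi: float = 1.0, b_pi: float = 99.0, a_e: float = 0.01,
                 b_e: float = 0.01, tau_sq: float = 1.0,
                 fixed_delta1_sq: float | None = None,
                 fixed_sigma_sq: float | None = None,
                 group_gamma: bool = False, random_state=None):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.delta0_sq = delta0_sq
        self.a_slab = a_slab
        self.b_slab = b_slab
        self.pi = pi
        self.a_pi = a_pi
        self.b_pi = b_pi
        self.a_e = a_e
        self.b_e = b_e
        self.tau_sq = tau_sq
        self.fixed_delta1_sq = fixed_delta1_sq
        self.fixed_sigma_sq = fixed_sigma_sq
        self.group_gamma = group_gamma
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X, y, covariates=None, blocks=None, annotations=None):
        """Run the Gibbs sampler.

        Parameters
        ----------
        X : ndarray, shape (n, m)
            Haplotype-cluster count design matrix H.
        y : ndarray, shape (n,)
        covariates : ndarray, shape (n, c), optional
            Fixed-effect covariates (include the intercept column); flat
            prior on their effects.
        blocks : ndarray of int, shape (m,), optional
            Block index of each column; defaults to one block per column.
        annotations : ndarray, shape (n_blocks, f), optional
            Block-level annotation features (standardized internally; an
            intercept column is prepended).  Activates the probit prior.
        """
        X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
        y = np.asarray(y, dtype=np.float64).ravel()
        n, m = X.shape
        if len(y) != n:
            raise ValueError("X and y have inconsistent sample counts")
        if not np.isfinite(X).all() or not np.isfinite(y).all():
            raise ValueError("non-finite values in X or y")
        if y.std() == 0:
            raise ValueError("phenotype has zero variance")
        if self.n_iter <= self.burn_in or self.burn_in < 0:
            raise ValueError("need n_iter > burn_in >= 0")
        block_of = (np.arange(m) if blocks is None
                    else np.asarray(blocks, dtype=np.int64))
        if len(block_of) != m:
            raise ValueError("blocks must map every design column")
        n_blocks = int(block_of.max()) + 1
        block_cols = [np.where(block_of == k)[0] for k in range(n_blocks)]
        rng = np.random.default_rng(self.random_state)

        C = None
        if covariates is not None:
            C = np.asarray(covariates, dtype=np.float64)
            if C.ndim == 1:
                C = C[:, None]
            if C.shape[0] != n:
                raise ValueError("covariates and y have inconsistent lengths")
            CtC = C.T @ C
            cf_C = cho_factor(CtC)
            U_C = cholesky(CtC, lower=False)

        A = theta = None
        if annotations is not None:
            F = np.asarray(annotations, dtype=np.float64)
            if F.ndim == 1:
                F = F[:, None]
            if F.shape[0] != n_blocks:
                raise ValueError("annotations must have one row per block")
            sd = F.std(axis=0)
            informative = sd > 0
            Fz = np.where(informative, (F - F.mean(axis=0)) / np.where(sd > 0, sd, 1.0), 0.0)
            A = np.column_stack([np.ones(n_blocks), Fz])
            cond = np.linalg.cond(A.T @ A)
            if cond > 1e8:
                logger.warning("annotation design nearly rank-deficient "
                               "(cond=%.2g); prior regularizes", cond)

        prior = SpikeSlabPrior(delta0_sq=self.delta0_sq, a=self.a_slab,
                               b=self.b_slab, pi=self.pi, a_pi=self.a_pi,
                               b_pi=self.b_pi, a_e=self.a_e, b_e=self.b_e,
                               tau_sq=self.tau_sq)
        d0 = prior.delta0_sq
        d1 = self.fixed_delta1_sq if self.fixed_delta1_sq is not None else 1.0
        sig2 = (self.fixed_sigma_sq if self.fixed_sigma_sq is not None
                else float(y.var()))
        update_slab = self.fixed_delta1_sq is None
        update_sigma = self.fixed_sigma_sq is None

        beta = np.zeros(m)
        gamma = np.zeros(m, dtype=np.int64)
        # pi is the *block*-level causality prior; cluster-level Bernoulli
        # probabilities are derived so that P(any cluster in block k
        # included a priori) equals pi_block[k].
        m_per_block = np.array([len(cols) for cols in block_cols], float)
        pi0 = prior.pi if prior.pi is not None else prior.a_pi / (prior.a_pi + prior.b_pi)
        pi_block = np.full(n_blocks, pi0)
        if A is not None:
            theta = np.zeros(A.shape[1])
            theta[0] = ndtri(pi0)
            theta_prior_mean = np.zeros(A.shape[1])
            theta_prior_mean[0] = ndtri(pi0)
            pi_block = np.clip(ndtr(A @ theta), 1e-6, 1 - 1e-6)

        def cluster_logit_pi(pib):
            if self.group_gamma:
                pv = pib[block_of]
            else:
                pv = 1.0 - (1.0 - pib[block_of]) ** (1.0 / m_per_block[block_of])
            pv = np.clip(pv, 1e-12, 1 - 1e-12)
            return pv, np.log(pv) - np.log1p(-pv)

        pi_vec, logit_pi = cluster_logit_pi(pi_block)

        alpha = None
        r = y.copy()
        if C is not None:
            alpha = cho_solve(cf_C, C.T @ y)
            r = y - C @ alpha
        Ht = np.ascontiguousarray(X.T)
        col_ss = (X * X).sum(axis=0)
        if self.group_gamma:
            gram = [X[:, cols].T @ X[:, cols] for cols in block_cols]

        n_keep = 0
        block_any = np.zeros(n_blocks)
        gamma_sum = np.zeros(m)
        beta_sum = np.zeros(m)
        beta_sq = np.zeros(m)
        alpha_sum = alpha_sq = None
        if C is not None:
            alpha_sum = np.zeros(C.shape[1])
            alpha_sq = np.zeros(C.shape[1])
        theta_sum = theta_sq = None
        theta_draws: list[np.ndarray] = []
        if A is not None:
            theta_sum = np.zeros(A.shape[1])
            theta_sq = np.zeros(A.shape[1])
        sig2_chain: list[float] = []
        d1_chain: list[float] = []
        pi_chain: list[float] = []
        total_flips = 0

        for it in range(self.n_iter):
            if C is not None:
                r_full = r + C @ alpha
                mean_a = cho_solve(cf_C, C.T @ r_full)
                noise = solve_triangular(
                    U_C, rng.standard_normal(C.shape[1])) * np.sqrt(sig2)
                alpha = mean_a + noise
                r = r_full - C @ alpha
            if self.group_gamma:
                flips = self._sweep_blocks(X, block_cols, gram, r, beta, gamma,
                                           logit_pi, d0, d1, sig2, rng)
            else:
                order = rng.permutation(m)
                u = rng.random(m)
                z = rng.standard_normal(m)
                flips = sweep_coefficients(Ht, col_ss, r, beta, gamma,
                                           logit_pi, d0, d1, sig2, order, u, z)
            total_flips += flips
            k1 = int(gamma.sum())
            if update_slab:
                ssq = float((beta[gamma == 1] ** 2).sum())
                prec1 = rng.gamma(prior.a + 0.5 * k1,
                                  1.0 / (prior.b + 0.5 * ssq))
                # keep the slab wider than the spike but no wider than the
                # phenotype scale allows; the diffuse Gamma prior otherwise
                # drifts to astronomical variances when nothing is included
                d1 = min(max(1.0 / prec1, 10.0 * d0), 100.0 * y.var())
            if update_sigma:
                sse = float(r @ r)
                prec_e = rng.gamma(prior.a_e + 0.5 * n,
                                   1.0 / (prior.b_e + 0.5 * sse))
                sig2 = 1.0 / prec_e
            blk_ind = np.array([gamma[cols].any() for cols in block_cols],
                               dtype=float)
            if A is not None:
                theta, _, pi_block = probit_prior_step(
                    blk_ind, A, theta, prior.tau_sq, rng,
                    prior_mean=theta_prior_mean)
                pi_vec, logit_pi = cluster_logit_pi(pi_block)
            elif prior.pi is None:
                k_blk = float(blk_ind.sum())
                pi_shared = rng.beta(prior.a_pi + k_blk,
                                     prior.b_pi + n_blocks - k_blk)
                pi_block[:] = min(max(pi_shared, 1e-6), 1 - 1e-6)
                pi_vec, logit_pi = cluster_logit_pi(pi_block)
            if not np.isfinite(r).all() or not np.isfinite(sig2):
                raise FloatingPointError(
                    f"non-finite sampler state at sweep {it}: "
                    f"sig2={sig2}, d1={d1}, |beta|max={np.abs(beta).max()}")
            if it >= self.burn_in and (it - self.burn_in) % self.thin == 0:
                n_keep += 1
                block_any += blk_ind
                gamma_sum += gamma
                beta_sum += beta
                beta_sq += beta ** 2
                if C is not None:
                    alpha_sum += alpha
                    alpha_sq += alpha ** 2
                if A is not None:
                    theta_sum += theta
                    theta_sq += theta ** 2
                    theta_draws.append(theta.copy())
                sig2_chain.append(sig2)
                d1_chain.append(d1)
                pi_chain.append(float(pi_block.mean()))

        beta_mean = beta_sum / n_keep
        beta_var = np.maximum(beta_sq / n_keep - beta_mean ** 2, 0.0)
        alpha_mean = alpha_sd = None
        if C is not None:
            alpha_mean = alpha_sum / n_keep
            alpha_sd = np.sqrt(np.maximum(alpha_sq / n_keep - alpha_mean ** 2,
                                          0.0))
        theta_mean = theta_sd = None
        if A is not None:
            theta_mean = theta_sum / n_keep
            theta_sd = np.sqrt(np.maximum(theta_sq / n_keep - theta_mean ** 2,
                                          0.0))
        diagnostics = {
            "n_draws": n_keep,
            "gamma_flip_rate": total_flips / (self.n_iter * m),
            "ess_delta1_sq": _ess(np.array(d1_chain)),
            "ess_sigma2": _ess(np.array(sig2_chain)),
        }
        self.summary_ = PosteriorSummary(
            block_pip=block_any / n_keep,
            cluster_pip=gamma_sum / n_keep,
            beta_mean=beta_mean,
            beta_sd=np.sqrt(beta_var),
            alpha_mean=alpha_mean,
            alpha_sd=alpha_sd,
            sigma2_mean=float(np.mean(sig2_chain)),
            delta1_sq_mean=float(np.mean(d1_chain)),
            pi_mean=float(np.mean(pi_chain)),
            theta_mean=theta_mean,
            theta_sd=theta_sd,
            block_of=block_of,
            diagnostics=diagnostics,
        )
        if theta_draws:
            self.theta_draws_ = np.array(theta_draws)
        self.pip_ = self.summary_.block_pip
        self.cluster_pip_ = self.summary_.cluster_pip
        self.beta_mean_ = beta_mean
        self.beta_sd_ = self.summary_.beta_sd
        self.alpha_mean_ = alpha_mean
        self.n_blocks_ = n_blocks
        return self

    # ------------------------------------------------------------------
    def _sweep_blocks(self, X, block_cols, gram, r, beta, gamma, logit_pi,
                      d0, d1, sig2, rng) -> int:
        """Block-level inclusion sweep (one gamma per block, joint beta)."""
        flips = 0
        for k in rng.permutation(len(block_cols)):
            cols = block_cols[k]
            Hb = X[:, cols]
            G = gram[k]
            mb = len(cols)
            r_t = r + Hb @ beta[cols]
            u = Hb.T @ r_t
            rtr = float(r_t @ r_t)

            def log_ml(d):
                M = np.eye(mb) + (d / sig2) * G
                cf = cho_factor(M)
                logdet = 2 * np.log(np.diag(cf[0])).sum()
                quad = (rtr - (d / sig2) * float(u @ cho_solve(cf, u))) / sig2
                return -0.5 * logdet - 0.5 * quad

            logit = logit_pi[cols[0]] + log_ml(d1) - log_ml(d0)
            p1 = 1.0 / (1.0 + np.exp(-np.clip(logit, -35, 35)))
            g_new = 1 if rng.random() < p1 else 0
            if g_new != gamma[cols[0]]:
                flips += 1
            gamma[cols] = g_new
            d = d1 if g_new else d0
            prec = G / sig2 + np.eye(mb) / d
            cf = cho_factor(prec)
            mean_b = cho_solve(cf, u / sig2)
            U = cholesky(prec, lower=False)
            b_new = mean_b + solve_triangular(U, rng.standard_normal(mb))
            r[:] = r_t - Hb @ b_new
            beta[cols] = b_new
        return flips

    def predict(self, X, covariates=None) -> np.ndarray:
        out = np.asarray(X, dtype=float) @ self.beta_mean_
        if covariates is not None and self.alpha_mean_ is not None:
            out = out + np.asarray(covariates, dtype=float) @ self.alpha_mean_
        return out


def run_gibbs(sample_table, design, prior: SpikeSlabPrior | None = None,
              annotations=None, iterations: int = 20_000,
              burn_in: int = 5_000, thin: int = 5, seed=None,
              group_gamma: bool = False) -> PosteriorSummary:
    """Functional wrapper: fine-map a :class:`~hapfm.clustering.HaplotypeDesign`."""
    prior = prior or SpikeSlabPrior()
    est = SpikeSlabFineMapper(
        n_iter=iterations, burn_in=burn_in, thin=thin,
        delta0_sq=prior.delta0_sq, a_slab=prior.a, b_slab=prior.b,
        pi=prior.pi, a_pi=prior.a_pi, b_pi=prior.b_pi, a_e=prior.a_e,
        b_e=prior.b_e, tau_sq=prior.tau_sq, group_gamma=group_gamma,
        random_state=seed)
    est.fit(design.H, sample_table.y, covariates=sample_table.C,
            blocks=design.block_of, annotations=annotations)
    return est.summary_
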