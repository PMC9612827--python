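"""Synthetic genotype and phenotype generation with full ground truth.

Genotypes: the genome is built from independent *parent blocks*, each split
into sub-blocks.  A sub-block of ``s`` SNPs carries ``h = h_c * d`` unique
haplotypes derived from ``h_c`` founder haplotypes (``d`` mutated
descendants each, per-site mutation rate ``mu``).  Haplotype frequencies
``f_h`` are obtained by solving ``f_s = Z' f_h`` (target allele frequencies
drawn Uniform(0.05, 0.95)) as a simplex-constrained least-squares problem,
and each individual draws two haplotypes per sub-block i.i.d. from ``f_h``
(Multinomial(2, f_h)).  Sub-blocks are drawn independently, so LD is strong
within a sub-block and near zero across block boundaries.

Phenotypes: y = C a + X eta + e.  Blocks become causal independently with
probability ``pi_b``; each causal block receives a total effect |eta_B| ~
Uniform(0.5, 3) distributed over its causal SNPs according to one of three
QTL architectures: (1) one large-effect SNP; (2) five to ten small-effect
SNPs (Dirichlet shares) whose causal alleles never co-occur on a single
unique haplotype of the block; (3) one SNP carrying a 50-80% share plus
small-effect SNPs as in (2).  Non-causal SNPs receive N(0, 1e-4) effects.
The residual is scaled so the realized heritability hits its target in
either per-locus or whole-trait mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .panel import GenotypePanel
from .partition import BlockPartition

logger = logging.getLogger("hapfm")


@dataclass
class SimGenotypeConfig:
    """Parameters of the block-structured genotype simulator."""

    n_individuals: int = 500
    n_parent_blocks: int = 100
    sub_blocks_range: tuple[int, int] = (1, 10)
    sub_block_size_range: tuple[int, int] = (10, 100)
    clusters_range: tuple[int, int] = (2, 4)
    diversity: int = 1
    mutation_rate: float = 0.02
    freq_range: tuple[float, float] = (0.05, 0.95)
    snp_spacing_bp: int = 100
    parent_gap_bp: int = 50_000
    chrom: str = "1"
    min_hap_freq: float = 0.02
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.diversity < 1:
            raise ValueError("diversity must be >= 1")
        if not (0 < self.mutation_rate < 0.5):
            raise ValueError("mutation_rate must lie in (0, 0.5)")


@dataclass
class SimPhenotypeConfig:
    """Parameters of the QTL-architecture phenotype simulator."""

    pi_b: float = 0.05
    effect_range: tuple[float, float] = (0.5, 3.0)
    architecture: int = 1
    heritability: float = 0.6
    mode: str = "trait"  # "trait" or "per_locus"
    n_covariates: int = 3  # including the intercept
    noncausal_sd: float = 0.01
    n_causal_blocks: int | None = None  # exact count instead of Bernoulli(pi_b)
    small_snp_range: tuple[int, int] = (5, 10)
    large_share_range: tuple[float, float] = (0.5, 0.8)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.pi_b <= 1):
            raise ValueError("pi_b must lie in [0, 1]")
        if not (0 <= self.heritability < 1):
            raise ValueError("heritability must lie in [0, 1)")
        if self.architecture not in (1, 2, 3):
            raise ValueError("architecture must be 1, 2 or 3")
        if self.mode not in ("trait", "per_locus"):
            raise ValueError("mode must be 'trait' or 'per_locus'")


@dataclass
class SimTruth:
    """Ground truth emitted by the simulators."""

    blocks: pd.DataFrame  # block_id, parent, chrom, snp_start, snp_end, h_c, d
    block_detail: list[dict]  # Z, founder_labels, f_h, f_s per block
    snps: pd.DataFrame | None = None  # chrom, pos, causal (lambda), effect (eta)
    causal_blocks: np.ndarray | None = None
    block_effects: np.ndarray | None = None
    architecture: int | None = None
    realized_h2: float | None = None
    covariate_effects: np.ndarray | None = None

    def partition(self) -> BlockPartition:
        blocks = [(str(r.chrom), int(r.snp_start), int(r.snp_end))
                  for r in self.blocks.itertuples(index=False)]
        return BlockPartition(blocks=blocks,
                              parent_block=self.blocks["parent"].to_numpy(),
                              method="simulated")


class SimulationError(RuntimeError):
    pass


def simulate_block_haplotypes(s: int, h_c: int, d: int, mu: float,
                              rng: np.random.Generator,
                              max_tries: int = 10_000):
    """Simulate ``h = h_c * d`` unique haplotypes from ``h_c`` founders.

    Founders are uniform random bit rows, rejected until pairwise Hamming
    distance >= s/4; any SNP column constant across founders is made
    polymorphic by flipping one founder's bit.  Each founder then spawns
    ``d`` descendants by independent per-site flips with probability
    ``mu``, rejecting duplicates and descendants that land strictly nearer
    to a foreign founder than to their own.

    Returns ``(Z, founder_labels)`` with rows grouped by founder.
    """
    if h_c * d > 2 ** s:
        raise ValueError("h_c * d exceeds the number of possible haplotypes")
    min_sep = max(1, int(np.ceil(s / 4)))
    for _ in range(max_tries):
        founders = rng.integers(0, 2, size=(h_c, s)).astype(np.uint8)
        const = (founders == founders[0]).all(axis=0)
        for j in np.where(const)[0]:
            founders[rng.integers(h_c), j] ^= 1
        dist = np.array([[np.sum(a != b) for b in founders] for a in founders])
        np.fill_diagonal(dist, s + 1)
        if dist.min() >= min_sep:
            break
    else:
        raise SimulationError("could not draw separated founders; "
                              "increase s or decrease h_c")
    rows: list[np.ndarray] = []
    labels: list[int] = []
    tries = 0
    for f in range(h_c):
        made = 0
        while made < d:
            tries += 1
            if tries > max_tries:
                raise SimulationError(
                    "descendant rejection budget exceeded; increase s or "
                    "decrease mu")
            cand = founders[f] ^ (rng.random(s) < mu).astype(np.uint8)
            if any((cand == r).all() for r in rows):
                continue
            dists = [int(np.sum(cand != founders[g])) for g in range(h_c)]
            if min(dists) < dists[f]:
                continue  # strictly nearer to a foreign founder
            rows.append(cand)
            labels.append(f)
            made += 1
    Z = np.array(rows, dtype=np.uint8)
    # mutations can make a column constant again; repair so every SNP stays
    # polymorphic among the unique haplotypes (flips cannot create duplicates)
    const = (Z == Z[0]).all(axis=0)
    for j in np.where(const)[0]:
        Z[rng.integers(len(Z)), j] ^= 1
    return Z, np.array(labels)


def solve_haplotype_frequencies(Z: np.ndarray, f_s: np.ndarray,
                                rng: np.random.Generator | None = None,
                                freq_range: tuple[float, float] = (0.05, 0.95),
                                min_hap_freq: float = 0.02,
                                tol: float = 0.40,
                                max_retries: int = 30) -> np.ndarray:
    """Solve ``f_s = Z' f_h`` for haplotype frequencies on the simplex.

    Minimizes ``||Z' f - f_s||^2`` subject to ``f >= min_hap_freq`` and
    ``sum f = 1`` (SLSQP).  The system is generally overdetermined (many
    more SNPs than haplotype degrees of freedom) so an exact solution
    rarely exists; if the root-mean-square per-SNP residual exceeds
    ``tol`` — a degenerate fit — the target frequencies are resampled
    within ``freq_range`` and the solve retried (logged); exceeding the
    retry budget is an error.
    """
    Z = np.asarray(Z, dtype=float)
    h, s = Z.shape
    f_s = np.asarray(f_s, dtype=float)
    if h * min_hap_freq >= 1.0:
        min_hap_freq = 0.5 / h
    if h == 1:
        return np.array([1.0])

    def solve_once(target):
        x0 = np.full(h, 1.0 / h)

        def obj(f):
            e = Z.T @ f - target
            return float(e @ e)

        def grad(f):
            return 2.0 * (Z @ (Z.T @ f - target))

        res = minimize(obj, x0, jac=grad, method="SLSQP",
                       bounds=[(min_hap_freq, 1.0)] * h,
                       constraints=[{"type": "eq",
                                     "fun": lambda f: f.sum() - 1.0,
                                     "jac": lambda f: np.ones(h)}],
                       options={"maxiter": 200, "ftol": 1e-12})
        f = np.clip(res.x, min_hap_freq, None)
        return f / f.sum()

    target = f_s
    for attempt in range(max_retries):
        f_h = solve_once(target)
        resid = Z.T @ f_h - target
        rms = float(np.sqrt((resid ** 2).mean()))
        if rms <= tol:
            return f_h
        if rng is None:
            break
        logger.info("frequency solve RMS residual %.3f > %.3f; resampling "
                    "targets (attempt %d)", rms, tol, attempt + 1)
        target = rng.uniform(*freq_range, size=s)
    raise SimulationError("haplotype frequency solve failed within the retry "
                          "budget")


def simulate_genotypes(cfg: SimGenotypeConfig):
    """Simulate a block-structured phased panel; returns ``(panel, truth)``."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_individuals
    sample_ids = [f"S{i:04d}" for i in range(n)]
    hap_cols: list[np.ndarray] = []
    positions: list[int] = []
    block_rows: list[dict] = []
    detail: list[dict] = []
    pos = 1
    snp_cursor = 0
    block_id = 0
    for parent in range(cfg.n_parent_blocks):
        n_sub = int(rng.integers(cfg.sub_blocks_range[0],
                                 cfg.sub_blocks_range[1] + 1))
        for _ in range(n_sub):
            s = int(rng.integers(cfg.sub_block_size_range[0],
                                 cfg.sub_block_size_range[1] + 1))
            h_c = int(rng.integers(cfg.clusters_range[0],
                                   cfg.clusters_range[1] + 1))
            Z, founder_labels = simulate_block_haplotypes(
                s, h_c, cfg.diversity, cfg.mutation_rate, rng)
            f_s = rng.uniform(*cfg.freq_range, size=s)
            f_h = solve_haplotype_frequencies(
                Z, f_s, rng=rng, freq_range=cfg.freq_range,
                min_hap_freq=cfg.min_hap_freq)
            # two haplotypes per individual, i.i.d. categorical = Multinomial(2, f_h)
            for attempt in range(50):
                draws = rng.choice(len(f_h), size=2 * n, p=f_h)
                block_hap = Z[draws]  # (2n, s)
                freq = block_hap.mean(axis=0)
                if np.all((freq > 0) & (freq < 1)):
                    break
            else:
                raise SimulationError("block stayed monomorphic after redraws")
            hap_cols.append(block_hap)
            positions.extend(range(pos, pos + s * cfg.snp_spacing_bp,
                                   cfg.snp_spacing_bp))
            block_rows.append(dict(block_id=block_id, parent=parent,
                                   chrom=cfg.chrom, snp_start=snp_cursor,
                                   snp_end=snp_cursor + s, h_c=h_c,
                                   d=cfg.diversity))
            detail.append(dict(Z=Z, founder_labels=founder_labels, f_h=f_h,
                               f_s=f_s, draws=draws))
            pos += s * cfg.snp_spacing_bp
            snp_cursor += s
            block_id += 1
        pos += cfg.parent_gap_bp
    hap = np.concatenate(hap_cols, axis=1)
    p = hap.shape[1]
    panel = GenotypePanel(
        sample_ids=sample_ids,
        chrom=np.full(p, cfg.chrom, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        ref=np.full(p, "A", dtype=object),
        alt=np.full(p, "T", dtype=object),
        haplotypes=hap,
    )
    truth = SimTruth(blocks=pd.DataFrame(block_rows), block_detail=detail)
    return panel, truth


def _pick_causal_sets(panel: GenotypePanel, block: tuple[str, int, int],
                      cfg: SimPhenotypeConfig, rng: np.random.Generator):
    """Choose causal SNP indices + effect shares for one block.

    Returns ``(snp_indices, shares)`` (both relative to the block) or None
    if the block admits no layout under the co-occurrence constraint.
    """
    _, s0, e0 = block
    size = e0 - s0
    uniq = np.unique(panel.haplotypes[:, s0:e0], axis=0)

    def admissible(idx):
        # reject if all causal (ALT) alleles co-occur on one unique haplotype
        return not np.any(uniq[:, idx].all(axis=1))

    if cfg.architecture == 1:
        j = int(rng.integers(size))
        return np.array([j]), np.array([1.0])
    lo, hi = cfg.small_snp_range
    need_large = cfg.architecture == 3
    min_needed = lo + (1 if need_large else 0)
    if size < min_needed:
        return None
    for _ in range(100):
        k = int(rng.integers(lo, min(hi, size - (1 if need_large else 0)) + 1))
        if need_large:
            chosen = rng.choice(size, size=k + 1, replace=False)
            large, small = chosen[0], chosen[1:]
            if not admissible(chosen):
                continue
            share = rng.uniform(*cfg.large_share_range)
            w = rng.dirichlet(np.ones(k)) * (1.0 - share)
            idx = np.concatenate([[large], small])
            shares = np.concatenate([[share], w])
        else:
            idx = rng.choice(size, size=k, replace=False)
            if not admissible(idx):
                continue
            shares = rng.dirichlet(np.ones(k))
        return idx, shares
    return None


def simulate_phenotypes(panel: GenotypePanel, partition: BlockPartition,
                        cfg: SimPhenotypeConfig):
    """Simulate a phenotype over a partitioned panel.

    Returns ``(sample_table, truth)`` where truth records per-SNP causal
    indicators and effects, per-block causal flags and total effects, and
    the realized heritability.
    """
    from .io import SampleTable

    rng = np.random.default_rng(cfg.seed)
    n, p = panel.n_samples, panel.n_snps
    X = panel.dosages.astype(np.float64)
    B = partition.n_blocks
    c = cfg.n_covariates
    C = np.column_stack([np.ones(n)] + [rng.uniform(-5, 5, size=n)
                                        for _ in range(c - 1)])
    alpha = rng.uniform(-1, 1, size=c)

    zero_h2 = cfg.heritability == 0
    if cfg.n_causal_blocks is not None:
        causal = np.zeros(B, dtype=bool)
        causal[rng.choice(B, size=cfg.n_causal_blocks, replace=False)] = True
    else:
        causal = rng.random(B) < cfg.pi_b
        if not causal.any():
            causal[rng.integers(B)] = True  # at least one causal block
    if zero_h2:
        causal[:] = False

    eta = np.zeros(p)
    lam = np.zeros(p, dtype=np.int64)
    block_eff = np.zeros(B)
    if not zero_h2:
        eta = rng.normal(0.0, cfg.noncausal_sd, size=p)
        for k in np.where(causal)[0]:
            blk = partition.blocks[k]
            picked = _pick_causal_sets(panel, blk, cfg, rng)
            tries = 0
            while picked is None:
                tries += 1
                if tries > 100:
                    raise SimulationError(
                        "no block admits the requested architecture")
                causal[k] = False
                new = int(rng.integers(B))
                logger.info("block %d cannot host architecture %d; "
                            "resampling causal block", k, cfg.architecture)
                if causal[new]:
                    continue
                causal[new] = True
                k = new
                blk = partition.blocks[k]
                picked = _pick_causal_sets(panel, blk, cfg, rng)
            idx, shares = picked
            mag = rng.uniform(*cfg.effect_range)
            sign = rng.choice([-1.0, 1.0])
            eff = sign * mag * shares
            snp_idx = blk[1] + idx
            eta[snp_idx] = eff
            lam[snp_idx] = 1
            block_eff[k] = eff.sum()

    def center_var(v):
        return float(np.var(v))

    if zero_h2:
        g = np.zeros(n)
        eps = rng.normal(size=n)
    else:
        if cfg.mode == "per_locus":
            # scale each causal block's contribution to unit realized variance
            for k in np.where(causal)[0]:
                _, s0, e0 = partition.blocks[k]
                gk = X[:, s0:e0] @ eta[s0:e0]
                vk = center_var(gk)
                if vk <= 0:
                    raise SimulationError("causal block with zero variance")
                eta[s0:e0] /= np.sqrt(vk)
            g = X @ eta
            var_g = center_var(g)
            target_eps = 1.0 / cfg.heritability - var_g
            if target_eps <= 0:
                raise SimulationError(
                    "per-locus heritability infeasible with this many causal "
                    "blocks; use trait mode or lower the target")
            # effects were rescaled: refresh the per-block totals
            for k in np.where(causal)[0]:
                _, s0, e0 = partition.blocks[k]
                block_eff[k] = (eta[s0:e0] * (lam[s0:e0] == 1)).sum()
        else:
            g = X @ eta
            var_g = center_var(g)
            target_eps = var_g * (1.0 - cfg.heritability) / cfg.heritability
        eps = rng.normal(size=n)
        # orthogonalize against the genetic value so realized variances add
        gc = g - g.mean()
        eps = eps - eps.mean()
        if gc @ gc > 0:
            eps = eps - (eps @ gc) / (gc @ gc) * gc
        eps *= np.sqrt(target_eps / center_var(eps))
    y = C @ alpha + g + eps
    var_g = center_var(g)
    realized_h2 = var_g / (var_g + center_var(eps)) if not zero_h2 else 0.0

    snps = pd.DataFrame(dict(chrom=panel.chrom, pos=panel.pos, causal=lam,
                             effect=eta))
    truth = SimTruth(
        blocks=pd.DataFrame([
            dict(block_id=k, parent=int(partition.parent_block[k]),
                 chrom=cb, snp_start=s0, snp_end=e0, h_c=-1, d=-1)
            for k, (cb, s0, e0) in enumerate(partition.blocks)]),
        block_detail=[],
        snps=snps,
        causal_blocks=causal,
        block_effects=block_eff,
        architecture=cfg.architecture,
        realized_h2=realized_h2,
        covariate_effects=alpha,
    )
    table = SampleTable(y=y, C=C, sample_ids=list(panel.sample_ids),
                        covariate_names=[f"cov{i}" for i in range(c)])
    return table, truth
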