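"""Per-block unique haplotype enumeration and clustering.

Within each haplotype block the distinct haplotypes observed among the 2n
sample haplotypes form the rows of a binary indicator matrix ``Z`` (h x s).
When h exceeds a user threshold the rows are clustered — by X-means (BIC
driven splitting of weighted k-means) or KNN-spectral clustering — so each
block contributes a bounded number of design variables.  The resulting
design matrix ``H`` (n x m) counts, per sample, how many of its two
haplotypes fall in each cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.neighbors import kneighbors_graph

from .panel import GenotypePanel
from .partition import BlockPartition

logger = logging.getLogger("hapfm")


@dataclass
class BlockHaplotypes:
    """Unique haplotypes of one block.

    ``Z`` is the h x s SNP indicator matrix, ``counts`` the occurrences of
    each unique haplotype among the 2n sample haplotypes, and ``assignment``
    maps each of the 2n phased haplotypes to its row of ``Z``.  Rows are
    ordered by descending count, ties broken lexicographically.
    """

    Z: np.ndarray
    counts: np.ndarray
    assignment: np.ndarray

    @property
    def h(self) -> int:
        return self.Z.shape[0]

    @property
    def s(self) -> int:
        return self.Z.shape[1]


@dataclass
class HaplotypeDesign:
    """Genome-wide haplotype-cluster design.

    ``H`` is the n x m count matrix (entries 0/1/2; within each block every
    sample's counts sum to 2), ``block_of`` maps each column to its block
    index, and ``cluster_members`` lists, per column, the unique-haplotype
    rows merged into that cluster.
    """

    H: np.ndarray
    block_of: np.ndarray
    cluster_members: list[np.ndarray]
    block_haplotypes: list[BlockHaplotypes]
    labels: list[np.ndarray]

    @property
    def m(self) -> int:
        return self.H.shape[1]

    @property
    def n_blocks(self) -> int:
        return len(self.block_haplotypes)

    def block_columns(self, k: int) -> np.ndarray:
        return np.where(self.block_of == k)[0]


def enumerate_haplotypes(panel: GenotypePanel,
                         block: tuple[str, int, int]) -> BlockHaplotypes:
    """Enumerate unique haplotypes over the block's SNPs."""
    _, s, e = block
    if not (0 <= s < e <= panel.n_snps):
        raise ValueError(f"block ({s}, {e}) outside panel bounds")
    rows = panel.haplotypes[:, s:e]
    uniq, inverse, counts = np.unique(rows, axis=0, return_inverse=True,
                                      return_counts=True)
    order = np.argsort(-counts, kind="stable")  # descending count, lex ties
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    return BlockHaplotypes(Z=uniq[order], counts=counts[order],
                           assignment=rank[inverse.ravel()])


def _weighted_bic(X: np.ndarray, w: np.ndarray, labels: np.ndarray,
                  centers: np.ndarray, var_floor: float = 0.04) -> float:
    """BIC of a weighted spherical-Gaussian k-means model (larger = better).

    The pooled variance is floored at ``var_floor``: binary haplotype rows
    are near-discrete, and without a floor the Gaussian likelihood degenerates
    as clusters shrink onto single rows, making BIC favour shattering every
    mutation into its own cluster.  The default treats per-site variation
    below ~4% (Bernoulli variance of a rare flip) as within-cluster noise.
    """
    k, d = centers.shape
    W = w.sum()
    sq = ((X - centers[labels]) ** 2).sum(axis=1)
    denom = max(W - k, 1.0)
    sigma2 = max((w * sq).sum() / (denom * d), var_floor)
    cluster_w = np.bincount(labels, weights=w, minlength=k)
    ll = 0.0
    for c in range(k):
        if cluster_w[c] > 0:
            ll += cluster_w[c] * np.log(cluster_w[c] / W)
    ll -= 0.5 * W * d * np.log(2 * np.pi * sigma2)
    ll -= (w * sq).sum() / (2 * sigma2)
    n_params = (k - 1) + k * d + 1
    return 2 * ll - n_params * np.log(W)


def _weighted_kmeans(X: np.ndarray, w: np.ndarray, k: int,
                     seed: int) -> tuple[np.ndarray, np.ndarray]:
    km = KMeans(n_clusters=k, n_init=1, init="k-means++",
                random_state=int(seed))
    labels = km.fit_predict(X, sample_weight=w)
    return labels, km.cluster_centers_


class XMeans(ClusterMixin, BaseEstimator):
    """X-means: weighted k-means with BIC-driven recursive cluster splitting.

    Starts from k = 2 and repeatedly splits the cluster whose 2-means split
    most improves the global spherical-Gaussian BIC, until no split helps or
    ``k_max`` is reached.

    Parameters
    ----------
    k_max : int, default 10
        Upper bound on the number of clusters.
    var_floor : float, default 0.04
        Variance floor of the BIC model (see :func:`_weighted_bic`).
    random_state : int or numpy Generator, optional
        Seeds the k-means++ initializations.
    """

    def __init__(self, k_max: int = 10, var_floor: float = 0.04,
                 random_state=None):
        self.k_max = k_max
        self.var_floor = var_floor
        self.random_state = random_state

    def fit(self, X, y=None, sample_weight=None) -> "XMeans":
        X = np.asarray(X, dtype=float)
        w = (np.ones(len(X)) if sample_weight is None
             else np.asarray(sample_weight, dtype=float))
        rng = np.random.default_rng(self.random_state)
        if len(X) < 2:
            self.labels_ = np.zeros(len(X), dtype=int)
            self.n_clusters_ = 1
            return self

        def centers_of(labels, k):
            return np.vstack([
                np.average(X[labels == c], axis=0, weights=w[labels == c])
                for c in range(k)])

        k0 = min(2, self.k_max)
        labels, _ = _weighted_kmeans(X, w, k0, rng.integers(2**31 - 1))
        k = len(np.unique(labels))
        labels = np.unique(labels, return_inverse=True)[1]
        best_bic = _weighted_bic(X, w, labels, centers_of(labels, k),
                                 self.var_floor)
        # greedily split whichever cluster most improves the *global* BIC;
        # per-cluster local comparisons over-split tiny near-discrete groups
        while k < self.k_max:
            best = None
            for c in range(k):
                members = np.where(labels == c)[0]
                if (len(members) < 2
                        or np.unique(X[members], axis=0).shape[0] < 2):
                    continue
                sub, _ = _weighted_kmeans(X[members], w[members], 2,
                                          rng.integers(2**31 - 1))
                if len(np.unique(sub)) < 2:
                    continue
                cand = labels.copy()
                cand[members[sub == 1]] = k
                bic = _weighted_bic(X, w, cand, centers_of(cand, k + 1),
                                    self.var_floor)
                if bic > best_bic and (best is None or bic > best[0]):
                    best = (bic, cand)
            if best is None:
                break
            best_bic, labels = best
            k += 1
        # compact labels in order of first occurrence
        order = {}
        for lab in labels:
            if lab not in order:
                order[lab] = len(order)
        self.labels_ = np.array([order[lab] for lab in labels])
        self.n_clusters_ = len(order)
        return self


class KNNSpectralClustering(ClusterMixin, BaseEstimator):
    """Spectral clustering on a symmetrized kNN graph over Hamming distance.

    Edges connect each row to its ``n_neighbors`` Hamming-nearest rows
    (symmetrized by union) and carry Gaussian similarity weights
    ``exp(-d^2 / (2 sigma^2))`` with a global bandwidth set to the median
    kNN distance.  The cluster count is chosen by the eigengap of the
    normalized graph Laplacian (capped at ``k_max``); the final assignment
    is weighted k-means on the row-normalized spectral embedding.  If the
    graph has more connected components than ``k_max``, the components
    themselves are returned as clusters with a warning.
    """

    def __init__(self, n_neighbors: int = 5, k_max: int = 10,
                 random_state=None):
        self.n_neighbors = n_neighbors
        self.k_max = k_max
        self.random_state = random_state

    def fit(self, X, y=None, sample_weight=None) -> "KNNSpectralClustering":
        X = np.asarray(X, dtype=float)
        h = len(X)
        if h < 3:
            raise ValueError("KNN-spectral clustering needs at least 3 rows")
        w = (np.ones(h) if sample_weight is None
             else np.asarray(sample_weight, dtype=float))
        rng = np.random.default_rng(self.random_state)
        nn = min(self.n_neighbors, h - 1)
        G = kneighbors_graph(X, nn, metric="hamming", mode="connectivity",
                             include_self=False)
        mask = ((G + G.T) > 0)  # symmetrize by union
        n_comp, comp = connected_components(mask, directed=False)
        if n_comp > self.k_max:
            logger.warning("kNN graph has %d components > k_max=%d; using "
                           "components as clusters", n_comp, self.k_max)
            self.labels_ = comp
            self.n_clusters_ = n_comp
            return self
        diff = X[:, None, :] != X[None, :, :]
        dist = diff.mean(axis=2)  # pairwise Hamming distance (fraction)
        # global bandwidth: median distance to the 3rd-nearest neighbour,
        # so edge weights resolve structure even on a complete graph
        knn_d = np.sort(dist, axis=1)[:, min(nn, 3)]
        sigma = max(float(np.median(knn_d)), 1e-6)
        A = np.exp(-(dist ** 2) / (2 * sigma ** 2)) * mask.toarray()
        deg = A.sum(axis=1)
        dinv = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
        L = np.eye(h) - dinv[:, None] * A * dinv[None, :]
        evals, evecs = eigh(L)
        k_hi = min(self.k_max, h - 1)
        gaps = np.diff(evals[: k_hi + 1])
        k = int(np.argmax(gaps[1:])) + 2 if k_hi >= 2 else 1  # k in 2..k_hi
        k = max(k, n_comp)
        emb = evecs[:, :k]
        norms = np.linalg.norm(emb, axis=1, keepdims=True)
        emb = emb / np.maximum(norms, 1e-12)
        labels, _ = _weighted_kmeans(emb, w, k, rng.integers(2**31 - 1))
        self.labels_ = labels
        self.n_clusters_ = k
        return self


def cluster_haplotypes(bh: BlockHaplotypes, method: str = "xmeans",
                       threshold: int = 10, k_max: int | None = None,
                       weighted: bool = False, n_neighbors: int = 5,
                       random_state=None) -> np.ndarray:
    """Cluster a block's unique haplotypes when they exceed the threshold.

    Blocks with ``h <= threshold`` keep the identity clustering (each unique
    haplotype its own cluster).  ``k_max`` defaults to the threshold.
    """
    if threshold < 2:
        raise ValueError("cluster threshold must be >= 2")
    if method not in ("xmeans", "knn_spectral", "none"):
        raise ValueError(f"unknown clustering method {method!r}")
    if method == "none" or bh.h <= threshold:
        return np.arange(bh.h)
    if k_max is None:
        k_max = threshold
    weights = bh.counts.astype(float) if weighted else None
    X = bh.Z.astype(float)
    if method == "xmeans":
        est = XMeans(k_max=k_max, random_state=random_state)
    else:
        est = KNNSpectralClustering(n_neighbors=n_neighbors, k_max=k_max,
                                    random_state=random_state)
    est.fit(X, sample_weight=weights)
    return est.labels_


def build_design_matrix(panel: GenotypePanel, partition: BlockPartition,
                        block_haps: list[BlockHaplotypes],
                        labels: list[np.ndarray]) -> HaplotypeDesign:
    """Assemble the n x m haplotype-cluster count design matrix H."""
    n = panel.n_samples
    cols: list[np.ndarray] = []
    block_of: list[int] = []
    members: list[np.ndarray] = []
    for k, (bh, lab) in enumerate(zip(block_haps, labels)):
        n_clusters = int(lab.max()) + 1
        hap_cluster = lab[bh.assignment]          # cluster of each 2n haplotype
        counts = np.zeros((n, n_clusters), dtype=np.int64)
        np.add.at(counts, (np.repeat(np.arange(n), 2), hap_cluster), 1)
        cols.append(counts)
        block_of.extend([k] * n_clusters)
        members.extend(np.where(lab == c)[0] for c in range(n_clusters))
    H = np.concatenate(cols, axis=1).astype(np.float64)
    return HaplotypeDesign(H=H, block_of=np.array(block_of),
                           cluster_members=members,
                           block_haplotypes=block_haps, labels=labels)


def make_design(panel: GenotypePanel, partition: BlockPartition,
                method: str = "xmeans", threshold: int = 10,
                k_max: int | None = None, weighted: bool = False,
                n_neighbors: int = 5, random_state=None) -> HaplotypeDesign:
    """Enumerate and cluster haplotypes for every block of a partition."""
    rng = np.random.default_rng(random_state)
    block_haps = [enumerate_haplotypes(panel, blk) for blk in partition.blocks]
    labels = [
        cluster_haplotypes(bh, method=method, threshold=threshold, k_max=k_max,
                           weighted=weighted, n_neighbors=n_neighbors,
                           random_state=rng)
        for bh in block_haps
    ]
    return build_design_matrix(panel, partition, block_haps, labels)
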