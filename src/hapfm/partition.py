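"""Genome-wide haplotype block partitioning.

Two-step strategy: first detect large *independent blocks* — maximal runs of
SNPs linked by at least one bridging pair with r^2 above a threshold — then
sub-partition each independent block, either into uniform windows or at LD
gaps (boundaries where the mean bridging r^2 is low).  Users can instead
supply their own partition as a BED-like file.

LD (r^2) is the squared Pearson correlation of the two SNP columns of the
phased ``(2n, p)`` haplotype matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .panel import GenotypePanel

logger = logging.getLogger("hapfm")


@dataclass
class BlockPartition:
    """Ordered, non-overlapping half-open SNP-index intervals tiling a panel.

    ``blocks[k] = (chrom, start, end)`` with *global* SNP indices into the
    panel; within a chromosome the intervals tile its index range exactly.
    """

    blocks: list[tuple[str, int, int]]
    parent_block: np.ndarray = None  # index of enclosing independent block
    method: str = "unknown"

    def __post_init__(self) -> None:
        if self.parent_block is None:
            self.parent_block = np.arange(len(self.blocks))
        self.parent_block = np.asarray(self.parent_block)
        for c, s, e in self.blocks:
            if e <= s:
                raise ValueError(f"empty block ({c}, {s}, {e})")
        # coverage + disjointness per chromosome
        prev_end = None
        prev_chrom = None
        for c, s, e in self.blocks:
            if c == prev_chrom and s != prev_end:
                raise ValueError(f"gap or overlap before SNP index {s} on {c}")
            prev_chrom, prev_end = c, e

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def sizes(self) -> np.ndarray:
        return np.array([e - s for _, s, e in self.blocks])

    def block_of_snp(self, n_snps: int) -> np.ndarray:
        out = np.full(n_snps, -1, dtype=np.int64)
        for k, (_, s, e) in enumerate(self.blocks):
            out[s:e] = k
        return out

    def boundaries(self) -> set[tuple[str, int]]:
        """Internal breakpoints as (chrom, snp_index-of-first-SNP-after-break)."""
        cuts = set()
        for i in range(1, len(self.blocks)):
            c_prev, _, e_prev = self.blocks[i - 1]
            c, s, _ = self.blocks[i]
            if c == c_prev and s == e_prev:
                cuts.add((c, s))
        return cuts


def validate_tiling(partition: BlockPartition, panel: GenotypePanel) -> None:
    """Check the partition tiles every SNP of the panel exactly once."""
    covered = np.zeros(panel.n_snps, dtype=np.int64)
    for _, s, e in partition.blocks:
        covered[s:e] += 1
    if not (covered == 1).all():
        raise ValueError("partition does not tile the panel exactly once")


def compute_r2(panel: GenotypePanel, i: int, j: int) -> float:
    """Squared Pearson correlation of SNP columns i and j over 2n haplotypes."""
    x = panel.haplotypes[:, i].astype(float)
    y = panel.haplotypes[:, j].astype(float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("r^2 undefined for a monomorphic SNP")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


class LDMatrixView:
    """Lazily computed banded pairwise r^2 within a SNP lookahead window.

    ``band(i)[d-1]`` holds r^2(i, i+d) for d = 1..window (NaN beyond the
    chromosome edge or the maximum pair distance in bp).
    """

    def __init__(self, panel: GenotypePanel, window: int = 50,
                 max_pair_bp: int | None = 500_000):
        self.panel = panel
        self.window = int(window)
        self.max_pair_bp = max_pair_bp
        hap = panel.haplotypes.astype(np.float64)
        mu = hap.mean(axis=0)
        sd = hap.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("monomorphic SNPs present; apply a MAF filter first")
        self._z = (hap - mu) / sd  # standardized columns
        self._n2 = hap.shape[0]
        self._cache: dict[int, np.ndarray] = {}

    def band(self, i: int) -> np.ndarray:
        got = self._cache.get(i)
        if got is not None:
            return got
        p = self.panel.n_snps
        hi = min(p, i + 1 + self.window)
        out = np.full(self.window, np.nan)
        if hi > i + 1:
            r = self._z[:, i] @ self._z[:, i + 1:hi] / self._n2
            vals = r * r
            # mask cross-chromosome and over-distance pairs
            same = self.panel.chrom[i + 1:hi] == self.panel.chrom[i]
            vals[~same.astype(bool)] = np.nan
            if self.max_pair_bp is not None:
                far = self.panel.pos[i + 1:hi] - self.panel.pos[i] > self.max_pair_bp
                vals[far] = np.nan
            out[: hi - i - 1] = vals
        self._cache[i] = out
        return out

    def r2(self, i: int, j: int) -> float:
        if i == j:
            return 1.0
        a, b = min(i, j), max(i, j)
        if b - a <= self.window:
            v = self.band(a)[b - a - 1]
            if not np.isnan(v):
                return float(v)
        return compute_r2(self.panel, a, b)


def find_independent_blocks(
    panel: GenotypePanel,
    r2_threshold: float = 0.1,
    ld_window: int = 50,
    max_pair_bp: int = 500_000,
    max_span_bp: int = 1_000_000,
    ld: LDMatrixView | None = None,
) -> BlockPartition:
    """Greedy left-to-right scan for large independent blocks.

    The current block extends past the boundary after SNP ``i`` while at
    least one pair (a, b) with a <= i < b, b - a <= ``ld_window`` and
    pos[b] - pos[a] <= ``max_pair_bp`` has r^2 >= ``r2_threshold``; a break
    is placed when no bridging pair qualifies or when extending would push
    the block span beyond ``max_span_bp``.
    """
    if not (0 < r2_threshold < 1):
        raise ValueError("r2_threshold must be in (0, 1)")
    if ld is None:
        ld = LDMatrixView(panel, window=ld_window, max_pair_bp=max_pair_bp)
    p = panel.n_snps
    # reach[a] = largest b with r2(a,b) >= threshold under window/bp limits
    reach = np.arange(p)
    for a in range(p):
        band = ld.band(a)
        ok = np.where(band >= r2_threshold)[0]
        if ok.size:
            reach[a] = a + 1 + ok[-1]
    blocks: list[tuple[str, int, int]] = []
    start = 0
    for i in range(p):
        last = i == p - 1
        new_chrom = not last and panel.chrom[i + 1] != panel.chrom[i]
        if last or new_chrom:
            blocks.append((str(panel.chrom[i]), start, i + 1))
            start = i + 1
            continue
        span_next = panel.pos[i + 1] - panel.pos[start]
        lo = max(start, i - ld.window + 1)
        bridged = reach[lo: i + 1].max() > i
        if not bridged or span_next > max_span_bp:
            blocks.append((str(panel.chrom[i]), start, i + 1))
            start = i + 1
    return BlockPartition(blocks=blocks, method="independent")


def partition_uniform(parent_block: tuple[str, int, int],
                      block_size: int) -> list[tuple[str, int, int]]:
    """Cut a block into consecutive windows of ``block_size`` SNPs."""
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    c, s, e = parent_block
    return [(c, a, min(a + block_size, e)) for a in range(s, e, block_size)]


def _boundary_means(ld: LDMatrixView, s: int, e: int) -> np.ndarray:
    """Mean bridging r^2 at each internal boundary j (first SNP of right part).

    Bridging pairs are (a, b) with a < j <= b, b - a <= window, both inside
    [s, e).  Returns an array aligned to boundaries s+1..e-1.
    """
    w = ld.window
    means = np.empty(e - s - 1)
    bands = [ld.band(a) for a in range(s, e - 1)]
    for idx, j in enumerate(range(s + 1, e)):
        tot = 0.0
        cnt = 0
        for a in range(max(s, j - w), j):
            band = bands[a - s]
            lo = j - a - 1          # first d index crossing the boundary
            hi = min(w, e - a - 1)  # stay inside the block
            seg = band[lo:hi]
            seg = seg[~np.isnan(seg)]
            tot += seg.sum()
            cnt += seg.size
        means[idx] = tot / cnt if cnt else np.inf
    return means


def partition_ld_gap(
    parent_block: tuple[str, int, int],
    panel: GenotypePanel,
    split_r2: float = 0.1,
    min_sub_size: int = 5,
    ld: LDMatrixView | None = None,
) -> list[tuple[str, int, int]]:
    """Recursively split a block at its weakest internal LD boundary.

    Every internal boundary is scored by the mean r^2 of bridging pairs
    within the LD window; the block splits at the minimizing boundary
    (leftmost on ties) if that mean is below ``split_r2`` and both halves
    keep at least ``min_sub_size`` SNPs, then recursion continues on the
    halves.
    """
    if ld is None:
        ld = LDMatrixView(panel)
    c, s, e = parent_block
    means = _boundary_means(ld, s, e) if e - s >= 2 else np.empty(0)

    out: list[tuple[str, int, int]] = []

    def recurse(a: int, b: int) -> None:
        if b - a < 2 * min_sub_size:
            out.append((c, a, b))
            return
        cand = np.arange(a + min_sub_size, b - min_sub_size + 1)
        vals = means[cand - s - 1]
        k = int(np.argmin(vals))  # leftmost minimizer
        if vals[k] < split_r2:
            j = int(cand[k])
            recurse(a, j)
            recurse(j, b)
        else:
            out.append((c, a, b))

    recurse(s, e)
    return out


def subpartition(
    partition: BlockPartition,
    panel: GenotypePanel,
    method: str = "ldgap",
    split_r2: float = 0.1,
    min_sub_size: int = 5,
    uniform_size: int = 20,
    ld: LDMatrixView | None = None,
) -> BlockPartition:
    """Apply a sub-partition method to every independent block."""
    if ld is None and method == "ldgap":
        ld = LDMatrixView(panel)
    blocks: list[tuple[str, int, int]] = []
    parents: list[int] = []
    for k, blk in enumerate(partition.blocks):
        if method == "ldgap":
            subs = partition_ld_gap(blk, panel, split_r2=split_r2,
                                    min_sub_size=min_sub_size, ld=ld)
        elif method == "uniform":
            subs = partition_uniform(blk, uniform_size)
        elif method == "none":
            subs = [blk]
        else:
            raise ValueError(f"unknown sub-partition method {method!r}")
        blocks.extend(subs)
        parents.extend([k] * len(subs))
    return BlockPartition(blocks=blocks, parent_block=np.array(parents),
                          method=f"independent+{method}")


class LDBlockPartitioner(BaseEstimator):
    """Two-step LD block partitioner with a scikit-learn style interface.

    Parameters
    ----------
    r2_threshold : float, default 0.1
        Minimum bridging r^2 for extending an independent block.
    ld_window : int, default 50
        SNP lookahead for bridging pairs.
    max_pair_bp : int, default 500_000
        Maximum pair distance in bp for bridging pairs.
    max_span_bp : int, default 1_000_000
        Hard cap on independent-block span.
    sub_method : {"ldgap", "uniform", "none"}, default "ldgap"
        Sub-partition strategy inside each independent block.
    split_r2 : float, default 0.1
        LD-gap split threshold on the mean bridging r^2.
    min_sub_size : int, default 5
        Minimum sub-block size in SNPs.
    uniform_size : int, default 20
        Window size for the uniform sub-partitioner.

    Attributes
    ----------
    independent_blocks_ : BlockPartition
        Step-1 partition into large independent blocks.
    blocks_ : BlockPartition
        Final (sub-)partition tiling the panel.
    """

    def __init__(self, r2_threshold: float = 0.1, ld_window: int = 50,
                 max_pair_bp: int = 500_000, max_span_bp: int = 1_000_000,
                 sub_method: str = "ldgap", split_r2: float = 0.1,
                 min_sub_size: int = 5, uniform_size: int = 20):
        self.r2_threshold = r2_threshold
        self.ld_window = ld_window
        self.max_pair_bp = max_pair_bp
        self.max_span_bp = max_span_bp
        self.sub_method = sub_method
        self.split_r2 = split_r2
        self.min_sub_size = min_sub_size
        self.uniform_size = uniform_size

    def fit(self, panel: GenotypePanel, y=None) -> "LDBlockPartitioner":
        ld = LDMatrixView(panel, window=self.ld_window,
                          max_pair_bp=self.max_pair_bp)
        self.independent_blocks_ = find_independent_blocks(
            panel, r2_threshold=self.r2_threshold, ld_window=self.ld_window,
            max_pair_bp=self.max_pair_bp, max_span_bp=self.max_span_bp, ld=ld)
        self.blocks_ = subpartition(
            self.independent_blocks_, panel, method=self.sub_method,
            split_r2=self.split_r2, min_sub_size=self.min_sub_size,
            uniform_size=self.uniform_size, ld=ld)
        validate_tiling(self.blocks_, panel)
        return self


def read_partition_file(path: str, panel: GenotypePanel) -> BlockPartition:
    """Import a user partition from a BED-like file (0-based half-open bp).

    Every panel SNP ends up in exactly one block: intervals are converted to
    SNP-index ranges, intervals containing no panel SNP are dropped with a
    warning, and runs of SNPs not covered by any interval become filler
    blocks (logged).
    """
    bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                      usecols=[0, 1, 2], names=["chrom", "start", "end"],
                      dtype={"chrom": str})
    assigned = np.full(panel.n_snps, -1, dtype=np.int64)
    intervals: list[tuple[int, int, int]] = []  # (order, snp_start, snp_end)
    for order, row in enumerate(bed.itertuples(index=False)):
        on_chrom = np.where(panel.chrom == row.chrom)[0]
        if on_chrom.size == 0:
            logger.warning("interval %s:%d-%d matches no panel chromosome; dropped",
                           row.chrom, row.start, row.end)
            continue
        cpos = panel.pos[on_chrom]
        lo = int(np.searchsorted(cpos, row.start + 1, side="left"))
        hi = int(np.searchsorted(cpos, row.end, side="right"))
        if hi <= lo:
            logger.warning("interval %s:%d-%d contains no panel SNP; dropped",
                           row.chrom, row.start, row.end)
            continue
        snp_lo, snp_hi = int(on_chrom[lo]), int(on_chrom[hi - 1]) + 1
        if np.any(assigned[snp_lo:snp_hi] >= 0):
            raise ValueError(
                f"overlapping partition intervals at {row.chrom}:{row.start}-{row.end}")
        assigned[snp_lo:snp_hi] = order
        intervals.append((order, snp_lo, snp_hi))
    # filler blocks over unassigned runs
    n_fillers = 0
    j = 0
    while j < panel.n_snps:
        if assigned[j] < 0:
            k = j
            while (k + 1 < panel.n_snps and assigned[k + 1] < 0
                   and panel.chrom[k + 1] == panel.chrom[j]):
                k += 1
            intervals.append((10**9 + j, j, k + 1))
            n_fillers += 1
            j = k + 1
        else:
            j += 1
    if n_fillers:
        logger.info("inserted %d filler blocks over uncovered SNPs", n_fillers)
    intervals.sort(key=lambda t: t[1])
    blocks = [(str(panel.chrom[s]), s, e) for _, s, e in intervals]
    part = BlockPartition(blocks=blocks, method="external")
    validate_tiling(part, panel)
    return part


def write_partition_bed(partition: BlockPartition, panel: GenotypePanel,
                        path: str) -> None:
    """Write the partition as BED (0-based half-open genomic intervals)."""
    with open(path, "w") as fh:
        for c, s, e in partition.blocks:
            fh.write(f"{c}\t{panel.pos[s] - 1}\t{panel.pos[e - 1]}\n")
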