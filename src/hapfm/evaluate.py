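"""Benchmark metrics: mapping power, true-positive rate, interval lengths,
the adjusted per-SNP FDR budget for SNP-level methods, and LD clumping.

A significant block is a true positive iff it physically contains at least
one truth causal SNP; mapping power is the fraction of truth causal blocks
recovered that way.  Interval lengths are the genomic spans of the
significant blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .panel import GenotypePanel
from .partition import BlockPartition

logger = logging.getLogger("hapfm")


@dataclass
class EvalReport:
    power: float
    tpr: float
    fpr_count: int
    interval_lengths: list[int]
    q: float
    n_significant: int
    n_causal_blocks: int
    empty_significant: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def score_blocks(significant: list[int], truth, partition: BlockPartition,
                 panel: GenotypePanel, q: float = 0.05) -> EvalReport:
    """Score a significant-block set against simulation truth.

    ``truth`` must expose ``snps`` (with ``causal``/``pos`` columns) and a
    truth partition via ``truth.partition()`` (or ``causal_blocks`` over the
    same partition).  Membership is decided by causal-SNP position, so the
    evaluated partition need not coincide with the truth partition.
    """
    if truth.snps is None or int(truth.snps["causal"].sum()) == 0:
        raise ValueError("truth contains no causal SNPs")
    causal_snp_idx = np.where(truth.snps["causal"].to_numpy() == 1)[0]
    significant = list(dict.fromkeys(int(b) for b in significant))

    # true positive: significant block containing >= 1 causal SNP
    tp_flags = []
    covered = np.zeros(len(causal_snp_idx), dtype=bool)
    for b in significant:
        _, s, e = partition.blocks[b]
        inside = (causal_snp_idx >= s) & (causal_snp_idx < e)
        tp_flags.append(bool(inside.any()))
        covered |= inside
    n_tp = int(np.sum(tp_flags))
    fpr_count = len(significant) - n_tp

    # power over truth causal blocks: detected iff any of its causal SNPs
    # falls inside some significant block
    truth_part = truth.partition()
    causal_blocks = (np.where(truth.causal_blocks)[0]
                     if truth.causal_blocks is not None else None)
    if causal_blocks is None:
        blk = truth_part.block_of_snp(len(truth.snps))
        causal_blocks = np.unique(blk[causal_snp_idx])
    n_detected = 0
    for k in causal_blocks:
        _, s, e = truth_part.blocks[k]
        idx = causal_snp_idx[(causal_snp_idx >= s) & (causal_snp_idx < e)]
        if covered[np.isin(causal_snp_idx, idx)].any():
            n_detected += 1
    power = n_detected / len(causal_blocks) if len(causal_blocks) else 0.0

    empty = len(significant) == 0
    tpr = 1.0 if empty else n_tp / len(significant)  # 1.0-by-convention
    lengths = [int(panel.pos[e - 1] - panel.pos[s] + 1)
               for _, s, e in (partition.blocks[b] for b in significant)]
    return EvalReport(power=float(power), tpr=float(tpr),
                      fpr_count=int(fpr_count), interval_lengths=lengths,
                      q=q, n_significant=len(significant),
                      n_causal_blocks=int(len(causal_blocks)),
                      empty_significant=empty)


def adjusted_fdr_threshold(n_representative: int, q: float,
                           n_total: int) -> float:
    """Per-SNP FDR budget |S| * q / M for SNP-level methods.

    ``|S|`` is the number of representative (per-block) SNPs, ``q`` the
    block-level FDR target and ``M`` the total SNP count.
    """
    if not (0 < n_representative <= n_total):
        raise ValueError("need 0 < |S| <= M")
    if not (0 <= q < 1):
        raise ValueError("q must lie in [0, 1)")
    return n_representative * q / n_total


def representative_snps(pvalues: np.ndarray,
                        partition: BlockPartition) -> np.ndarray:
    """Most significant SNP index per block (helper for SNP-level methods)."""
    pvalues = np.asarray(pvalues, dtype=float)
    out = []
    for _, s, e in partition.blocks:
        out.append(s + int(np.argmin(pvalues[s:e])))
    return np.array(out)


def clump_snps(snp_stats: pd.DataFrame, panel: GenotypePanel,
               clump_r2: float = 0.2, window_kb: float = 250.0) -> list[dict]:
    """Greedy LD clumping of SNPs around index SNPs.

    ``snp_stats`` needs columns ``chrom``, ``pos``, ``p``.  Repeatedly the
    most significant unclaimed SNP becomes an index and absorbs all
    unclaimed SNPs within ``window_kb`` whose r^2 with it reaches
    ``clump_r2``.  Position ties are broken leftmost.  Returns a list of
    clumps with their index SNP, members and genomic span.
    """
    stats = snp_stats.reset_index(drop=True)
    if ((stats["p"] < 0) | (stats["p"] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    key = {(str(c), int(q)): j
           for j, (c, q) in enumerate(zip(panel.chrom, panel.pos))}
    snp_idx = np.array([key[(str(c), int(q))]
                        for c, q in zip(stats["chrom"], stats["pos"])])
    hap = panel.haplotypes.astype(float)
    mu, sd = hap.mean(axis=0), hap.std(axis=0)
    z = (hap - mu) / np.where(sd > 0, sd, 1.0)
    order = np.lexsort((stats["pos"].to_numpy(), stats["p"].to_numpy()))
    claimed = np.zeros(len(stats), dtype=bool)
    clumps = []
    for i in order:
        if claimed[i]:
            continue
        claimed[i] = True
        members = [i]
        same = (stats["chrom"].astype(str) == str(stats["chrom"][i])).to_numpy()
        near = np.abs(stats["pos"].to_numpy() - stats["pos"][i]) <= window_kb * 1000
        cand = np.where(same & near & ~claimed)[0]
        if cand.size:
            r = z[:, snp_idx[cand]].T @ z[:, snp_idx[i]] / hap.shape[0]
            absorb = cand[r * r >= clump_r2]
            claimed[absorb] = True
            members.extend(absorb.tolist())
        pos = stats["pos"].to_numpy()[members]
        clumps.append(dict(index_snp=int(stats["pos"][i]),
                           chrom=str(stats["chrom"][i]),
                           members=sorted(int(m) for m in members),
                           start=int(pos.min()), end=int(pos.max()),
                           span=int(pos.max() - pos.min() + 1)))
    return clumps
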