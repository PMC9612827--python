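"""Tabular I/O, run configuration and result serialization.

All coordinates follow the named standards: VCF positions are 1-based,
partition files are BED-like 0-based half-open, and internal block
representations are half-open SNP-index ranges.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .panel import GenotypePanel
from .partition import BlockPartition

logger = logging.getLogger("hapfm")


@dataclass
class SampleTable:
    """Phenotype and covariates aligned to a panel's sample order.

    ``C`` always carries a leading all-ones intercept column.
    """

    y: np.ndarray
    C: np.ndarray
    sample_ids: list[str]
    covariate_names: list[str]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64).ravel()
        self.C = np.asarray(self.C, dtype=np.float64)
        if self.C.ndim == 1:
            self.C = self.C[:, None]
        if len(self.y) != self.C.shape[0] or len(self.y) != len(self.sample_ids):
            raise ValueError("phenotype/covariate/sample length mismatch")
        if not np.isfinite(self.y).all() or not np.isfinite(self.C).all():
            raise ValueError("missing or non-numeric values in sample table")


@dataclass
class RunConfig:
    """Global configuration shared by the CLI subcommands."""

    r2_threshold: float = 0.1
    ld_window: int = 50
    max_pair_bp: int = 500_000
    max_span_bp: int = 1_000_000
    sub_method: str = "ldgap"
    split_r2: float = 0.1
    min_sub_size: int = 5
    uniform_size: int = 20
    cluster_threshold: int = 10
    clustering_method: str = "xmeans"
    min_maf: float = 0.01
    iterations: int = 20_000
    burn_in: int = 5_000
    thin: int = 5
    seed: int = 0
    fdr_q: float = 0.05
    delta0_sq: float = 1e-4
    a_slab: float = 0.1
    b_slab: float = 0.1
    pi: float | None = None
    a_pi: float = 1.0
    b_pi: float = 99.0

    def __post_init__(self) -> None:
        if not (0 < self.r2_threshold < 1):
            raise ValueError("r2_threshold must lie in (0, 1)")
        if self.iterations <= self.burn_in or self.burn_in < 0:
            raise ValueError("need iterations > burn_in >= 0")
        if self.cluster_threshold < 2:
            raise ValueError("cluster_threshold must be >= 2")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def read_sample_table(path: str, panel: GenotypePanel,
                      phenotype: str | None = None) -> SampleTable:
    """Read a TSV of phenotype + covariates and align it to the panel.

    The first column holds sample IDs; ``phenotype`` names the phenotype
    column (default: the first non-ID column); remaining numeric columns
    are covariates.  Rows are reordered to the panel's sample order and an
    all-ones intercept column is prepended if none is present.
    """
    df = pd.read_csv(path, sep="\t")
    id_col = df.columns[0]
    df[id_col] = df[id_col].astype(str)
    missing = [s for s in panel.sample_ids if s not in set(df[id_col])]
    if missing:
        raise ValueError(f"samples missing from table: {', '.join(missing)}")
    df = df.set_index(id_col).loc[panel.sample_ids]
    if phenotype is None:
        phenotype = df.columns[0]
    y = pd.to_numeric(df[phenotype], errors="coerce")
    if y.isna().any():
        bad = df.index[y.isna()].tolist()
        raise ValueError(f"non-numeric phenotype for samples: {bad}")
    cov = df.drop(columns=[phenotype])
    cov = cov.apply(pd.to_numeric, errors="coerce")
    if cov.isna().any().any():
        raise ValueError("non-numeric covariate values")
    names = list(cov.columns)
    Cmat = cov.to_numpy(dtype=float) if names else np.empty((len(df), 0))
    has_intercept = any(np.allclose(Cmat[:, j], 1.0) for j in range(Cmat.shape[1]))
    if not has_intercept:
        Cmat = np.column_stack([np.ones(len(df)), Cmat])
        names = ["intercept"] + names
    return SampleTable(y=y.to_numpy(dtype=float), C=Cmat,
                       sample_ids=list(panel.sample_ids),
                       covariate_names=names)


def read_annotation_table(path: str, n_blocks: int) -> np.ndarray:
    """Read a per-block annotation TSV (first column: block id, 0-based)."""
    df = pd.read_csv(path, sep="\t")
    idx = df.iloc[:, 0].to_numpy(dtype=int)
    if sorted(idx.tolist()) != list(range(n_blocks)):
        raise ValueError("annotation table must cover every block exactly once")
    feats = df.iloc[np.argsort(idx), 1:].to_numpy(dtype=float)
    return feats


RESULT_COLUMNS = ["chrom", "start", "end", "n_snps", "n_clusters", "pip",
                  "effect_size", "fdr_rank", "significant"]


def write_block_results(result, partition: BlockPartition,
                        panel: GenotypePanel, path: str,
                        q: float = 0.05) -> pd.DataFrame:
    """Write the per-block fine-mapping results table.

    One row per block with the block span (1-based first/last SNP
    position), its PIP, the largest absolute posterior-mean cluster effect,
    the PIP rank and the 0/1 significance call at FDR ``q``.
    """
    from .finemap import select_significant

    if len(result.block_pip) != partition.n_blocks:
        raise ValueError("result and partition have different block counts")
    selected, _ = select_significant(result.block_pip, q=q)
    sig = np.zeros(partition.n_blocks, dtype=int)
    sig[selected] = 1
    order = np.argsort(-result.block_pip, kind="stable")
    rank = np.empty(partition.n_blocks, dtype=int)
    rank[order] = np.arange(1, partition.n_blocks + 1)
    eff = result.block_effect_size()
    rows = []
    for k, (c, s, e) in enumerate(partition.blocks):
        rows.append(dict(chrom=c, start=int(panel.pos[s]),
                         end=int(panel.pos[e - 1]), n_snps=e - s,
                         n_clusters=int((result.block_of == k).sum()),
                         pip=round(float(result.block_pip[k]), 6),
                         effect_size=round(float(eff[k]), 6),
                         fdr_rank=int(rank[k]), significant=int(sig[k])))
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return df


def read_block_results(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"result table missing columns: {sorted(missing)}")
    return df


def write_design(design, partition: BlockPartition, panel: GenotypePanel,
                 prefix: str) -> None:
    """Serialize a haplotype design as ``<prefix>.h.tsv`` + ``<prefix>.clusters.tsv``.

    The first file is the dense n x m count matrix (one row per sample);
    the second describes each cluster column: block, coordinates and the
    member unique-haplotype bitstrings.
    """
    hdr = [f"b{design.block_of[j]}c{j}" for j in range(design.m)]
    hdf = pd.DataFrame(design.H.astype(int), columns=hdr)
    hdf.insert(0, "sample", panel.sample_ids)
    hdf.to_csv(f"{prefix}.h.tsv", sep="\t", index=False)
    rows = []
    for j in range(design.m):
        k = int(design.block_of[j])
        c, s, e = partition.blocks[k]
        bh = design.block_haplotypes[k]
        local = j - int(np.nonzero(design.block_of == k)[0][0])
        members = np.where(design.labels[k] == local)[0]
        haps = ";".join("".join(map(str, bh.Z[r])) for r in members)
        rows.append(dict(column=j, block=k, chrom=c,
                         start=int(panel.pos[s]), end=int(panel.pos[e - 1]),
                         n_snps=e - s, haplotypes=haps))
    pd.DataFrame(rows).to_csv(f"{prefix}.clusters.tsv", sep="\t", index=False)


def write_truth(truth, panel: GenotypePanel, prefix: str) -> None:
    """Write simulator truth as ``<prefix>.blocks.tsv`` / ``<prefix>.snps.tsv``."""
    truth.blocks.to_csv(f"{prefix}.blocks.tsv", sep="\t", index=False)
    if truth.snps is not None:
        snps = truth.snps.copy()
        if truth.causal_blocks is not None:
            part = [(s, e) for _, s, e in
                    [(c, s, e) for c, s, e in
                     zip(truth.blocks.chrom, truth.blocks.snp_start,
                         truth.blocks.snp_end)]]
            block_of = np.full(len(snps), -1)
            for k, (s, e) in enumerate(part):
                block_of[s:e] = k
            snps["block"] = block_of
            snps["block_causal"] = truth.causal_blocks[block_of].astype(int)
        snps.to_csv(f"{prefix}.snps.tsv", sep="\t", index=False)


def write_json(obj: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
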