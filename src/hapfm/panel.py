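"""Phased genotype panel container and VCF I/O.

The panel stores phased biallelic SNP genotypes as a ``(2n, p)`` binary
haplotype matrix: rows ``2i`` and ``2i+1`` are the two phased haplotypes of
sample ``i``, entry 0 is the REF allele and 1 the ALT allele.  Diploid
dosages (0/1/2) are derived by summing the two haplotype rows per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("hapfm")


class PanelError(ValueError):
    """Raised for malformed or unsupported genotype input."""


@dataclass
class GenotypePanel:
    """Phased biallelic SNP panel.

    Parameters
    ----------
    sample_ids : list of str
        ``n`` sample identifiers.
    chrom : ndarray of str, shape (p,)
        Chromosome of each SNP, in file order.
    pos : ndarray of int, shape (p,)
        1-based coordinates, strictly increasing within each chromosome.
    ref, alt : ndarray of str, shape (p,)
        Reference / alternate alleles.
    haplotypes : ndarray of uint8, shape (2n, p)
        Phased haplotypes; 0 = REF, 1 = ALT.
    """

    sample_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    haplotypes: np.ndarray
    maf: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.uint8)
        n2, p = self.haplotypes.shape
        if n2 != 2 * len(self.sample_ids):
            raise PanelError(
                f"haplotype matrix has {n2} rows for {len(self.sample_ids)} samples"
            )
        if len(self.sample_ids) < 2:
            raise PanelError("a panel needs at least 2 samples")
        if p < 1 or len(self.pos) != p:
            raise PanelError("empty panel or position/haplotype length mismatch")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise PanelError("haplotype entries must be 0/1")
        for c in dict.fromkeys(self.chrom.tolist()):
            cp = self.pos[self.chrom == c]
            if np.any(np.diff(cp) <= 0):
                raise PanelError(f"positions not strictly increasing on {c}")
        freq = self.haplotypes.mean(axis=0)
        self.maf = np.minimum(freq, 1.0 - freq)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def dosages(self) -> np.ndarray:
        """(n, p) ALT-allele dosage matrix X with entries in {0, 1, 2}."""
        return (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(np.int8)

    def alt_freq(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def subset_snps(self, keep: np.ndarray) -> "GenotypePanel":
        keep = np.asarray(keep)
        return GenotypePanel(
            sample_ids=list(self.sample_ids),
            chrom=self.chrom[keep],
            pos=self.pos[keep],
            ref=self.ref[keep],
            alt=self.alt[keep],
            haplotypes=self.haplotypes[:, keep],
        )


def read_phased_vcf(
    path: str, min_maf: float = 0.0, drop_missing_sites: bool = False
) -> GenotypePanel:
    """Read a phased VCF into a :class:`GenotypePanel`.

    Only biallelic SNP records are retained (others are skipped with a logged
    count).  Every retained genotype must use the phased ``|`` separator; a
    missing genotype is an error unless ``drop_missing_sites`` is set, in
    which case the whole site is removed and logged.  SNPs with minor allele
    frequency below ``min_maf`` are filtered out.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    cols: list[np.ndarray] = []
    n_skipped_nonbiallelic = 0
    n_dropped_missing = 0
    seen: set[tuple[str, int]] = set()
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped_nonbiallelic += 1
            continue
        key = (var.CHROM, var.POS)
        if key in seen:
            raise PanelError(f"duplicated position {var.CHROM}:{var.POS}")
        seen.add(key)
        gts = var.genotypes  # list of [allele0, allele1, phased]
        col = np.empty(2 * len(sample_ids), dtype=np.int16)
        missing = False
        for i, g in enumerate(gts):
            a0, a1 = g[0], g[1]
            if a0 < 0 or a1 < 0:
                missing = True
                break
            if not g[-1]:
                raise PanelError(
                    f"unphased genotype for sample {sample_ids[i]} at "
                    f"{var.CHROM}:{var.POS}; phased input required"
                )
            col[2 * i] = a0
            col[2 * i + 1] = a1
        if missing:
            if drop_missing_sites:
                n_dropped_missing += 1
                continue
            raise PanelError(
                f"missing genotype at {var.CHROM}:{var.POS}; rerun with "
                "drop_missing_sites=True to remove such sites"
            )
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        cols.append(col)
    if n_skipped_nonbiallelic:
        logger.info("skipped %d non-biallelic/non-SNP records", n_skipped_nonbiallelic)
    if n_dropped_missing:
        logger.info("dropped %d sites with missing genotypes", n_dropped_missing)
    if not cols:
        raise PanelError(f"no usable biallelic SNP records in {path}")
    hap = np.stack(cols, axis=1).astype(np.uint8)
    panel = GenotypePanel(
        sample_ids=sample_ids,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        haplotypes=hap,
    )
    if min_maf > 0:
        keep = panel.maf >= min_maf
        n_filtered = int((~keep).sum())
        if n_filtered:
            logger.info("filtered %d SNPs with MAF < %g", n_filtered, min_maf)
        if not keep.any():
            raise PanelError("all SNPs removed by the MAF filter")
        panel = panel.subset_snps(keep)
    return panel


def write_phased_vcf(panel: GenotypePanel, path: str) -> None:
    """Write the panel as an uncompressed phased VCF via pysam."""
    import pysam

    header = pysam.VariantHeader()
    for c in dict.fromkeys(panel.chrom.tolist()):
        length = int(panel.pos[panel.chrom == c].max()) + 1000
        header.contigs.add(c, length=length)
    header.add_meta(
        "FORMAT",
        items=[("ID", "GT"), ("Number", "1"), ("Type", "String"),
               ("Description", "Genotype")],
    )
    for s in panel.sample_ids:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as out:
        hap = panel.haplotypes
        for j in range(panel.n_snps):
            rec = out.new_record(
                contig=str(panel.chrom[j]),
                start=int(panel.pos[j]) - 1,
                stop=int(panel.pos[j]),
                alleles=(str(panel.ref[j]), str(panel.alt[j])),
            )
            for i, s in enumerate(panel.sample_ids):
                rec.samples[s]["GT"] = (int(hap[2 * i, j]), int(hap[2 * i + 1, j]))
                rec.samples[s].phased = True
            out.write(rec)
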