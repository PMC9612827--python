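import numpy as np
import pytest

from hapfm import (LDBlockPartitioner, SimGenotypeConfig, SimPhenotypeConfig,
                   make_design, simulate_genotypes, simulate_phenotypes)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=1,length=100000>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_vcf(path, records, samples=("S1", "S2", "S3")):
    """Write a tiny VCF; ``records`` are (chrom, pos, ref, alt, gt-strings)."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for chrom, pos, ref, alt, gts in records:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")
    return str(path)


@pytest.fixture
def tiny_vcf(tmp_path):
    """3 samples x 4 phased biallelic SNPs with hand-readable genotypes."""
    records = [
        ("1", 100, "A", "T", ["0|1", "1|1", "0|0"]),
        ("1", 200, "C", "G", ["0|0", "0|1", "1|1"]),
        ("1", 300, "G", "A", ["1|0", "0|0", "0|1"]),
        ("1", 400, "T", "C", ["1|1", "1|0", "0|0"]),
    ]
    return write_vcf(tmp_path / "tiny.vcf", records)


@pytest.fixture(scope="session")
def sim_panel():
    """Small block-structured panel with ground-truth sub-block boundaries."""
    cfg = SimGenotypeConfig(n_individuals=300, n_parent_blocks=5,
                            diversity=3, seed=11)
    return simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def sim_pipeline(sim_panel):
    """Panel + fitted partition + design, shared by the slower tests."""
    panel, truth = sim_panel
    part = LDBlockPartitioner().fit(panel).blocks_
    design = make_design(panel, part, random_state=0)
    return panel, truth, part, design


@pytest.fixture(scope="session")
def sim_trait(sim_pipeline):
    """A single-causal-block trait on the shared panel."""
    panel, truth, part, design = sim_pipeline
    cfg = SimPhenotypeConfig(architecture=1, heritability=0.6, mode="trait",
                             n_causal_blocks=1, seed=21)
    table, ptruth = simulate_phenotypes(panel, part, cfg)
    return table, ptruth
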