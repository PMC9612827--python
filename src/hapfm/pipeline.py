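"""One-call convenience pipeline: partition -> cluster -> fine-map."""

from __future__ import annotations

import numpy as np

from .clustering import HaplotypeDesign, make_design
from .finemap import PosteriorSummary, SpikeSlabPrior, run_gibbs, select_significant
from .io import SampleTable
from .panel import GenotypePanel
from .partition import BlockPartition, LDBlockPartitioner


def fine_map_panel(
    panel: GenotypePanel,
    table: SampleTable,
    partition: BlockPartition | None = None,
    annotations=None,
    prior: SpikeSlabPrior | None = None,
    cluster_method: str = "xmeans",
    cluster_threshold: int = 10,
    iterations: int = 20_000,
    burn_in: int = 5_000,
    thin: int = 5,
    q: float = 0.05,
    seed: int | None = None,
    partitioner_kwargs: dict | None = None,
):
    """Run the full fine-mapping workflow on a phased panel.

    Returns ``(partition, design, summary, selected)`` where ``selected``
    is the Bayesian-FDR significant block list at level ``q``.
    """
    rng = np.random.default_rng(seed)
    if partition is None:
        est = LDBlockPartitioner(**(partitioner_kwargs or {}))
        partition = est.fit(panel).blocks_
    design = make_design(panel, partition, method=cluster_method,
                         threshold=cluster_threshold,
                         random_state=rng.integers(2**31 - 1))
    summary = run_gibbs(table, design, prior=prior, annotations=annotations,
                        iterations=iterations, burn_in=burn_in, thin=thin,
                        seed=rng.integers(2**31 - 1))
    selected, _ = select_significant(summary.block_pip, q=q)
    return partition, design, summary, selected
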