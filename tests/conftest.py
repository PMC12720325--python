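import numpy as np
import pytest

from hrepipe.core_io import (
    Condition,
    ExpressionMatrix,
    GeneModel,
    Genotype,
    GenomicInterval,
    SampleMeta,
    Scale,
)
from hrepipe.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def noise_free_dataset():
    cfg = SimulationConfig(n_genes=60, noise_sd=0.0, n_decoy_peaks=10, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture
def plus_gene():
    return GeneModel(
        gene_id="gA",
        interval=GenomicInterval("chr1", 10_000, 12_000, "+"),
        strand="+",
        exons=(
            GenomicInterval("chr1", 10_000, 10_500, "+"),
            GenomicInterval("chr1", 11_500, 12_000, "+"),
        ),
    )


@pytest.fixture
def minus_gene():
    return GeneModel(
        gene_id="gB",
        interval=GenomicInterval("chr1", 8_001, 10_001, "-"),
        strand="-",
    )


def make_matrix(values, gene_ids=None, design=None, scale=Scale.LOG2TPM):
    """Small expression matrix helper.

    ``design`` is a list of (genotype, condition, timepoint) tuples, one
    per column; defaults to WT/none/0 placeholders.
    """
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    if design is None:
        design = [(Genotype.WT, Condition.NONE, 0.0)] * n_samples
    samples = [
        SampleMeta(f"s{i}", gt, cond, tp, 1)
        for i, (gt, cond, tp) in enumerate(design)
    ]
    return ExpressionMatrix(list(gene_ids), samples, values, scale)
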