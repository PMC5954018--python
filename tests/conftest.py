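"""Shared fixtures: the default seeded synthetic dataset and small helpers."""

import numpy as np
import pandas as pd
import pytest

from lnclink.models import CountMatrix, SampleTable
from lnclink.synthetic import SimConfig, simulate_counts, simulate_genome

DEFAULT_SEED = 1729


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    """(genes, sequences, truth, counts) for the default study conditions."""
    genes, sequences, truth = simulate_genome(default_config)
    counts = simulate_counts(default_config, genes, truth)
    return genes, sequences, truth, counts


@pytest.fixture(scope="session")
def make_counts():
    """Factory fixture for small literal count matrices."""
    return _make_counts


def _make_counts(values, sample_ids=None, conditions=None, gene_ids=None,
                 mapped=None) -> CountMatrix:
    """Small literal count matrix helper."""
    arr = np.asarray(values, dtype=np.int64)
    n_genes, n_samples = arr.shape
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(n_samples)]
    if conditions is None:
        half = n_samples // 2
        conditions = ["control"] * half + ["case"] * (n_samples - half)
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(n_genes)]
    counts = pd.DataFrame(arr, index=gene_ids, columns=sample_ids)
    counts.index.name = "gene_id"
    samples = SampleTable(sample_ids=sample_ids, conditions=conditions,
                          mapped_reads_millions=mapped)
    return CountMatrix(counts=counts, samples=samples)
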