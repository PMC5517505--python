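import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ogdrseq import CountMatrix

settings.register_profile("deterministic", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("deterministic")


def make_count_matrix(counts, lengths, totals, gene_ids=None, sample_ids=None) -> CountMatrix:
    counts = np.asarray(counts)
    g, s = counts.shape
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(g)]
    sample_ids = sample_ids or [f"S{j + 1}" for j in range(s)]
    idx = pd.Index(gene_ids, name="gene_id")
    return CountMatrix(
        counts=pd.DataFrame(counts, index=idx, columns=sample_ids),
        lengths=pd.Series(lengths, index=idx, name="length_bp"),
        totals=pd.Series(totals, index=pd.Index(sample_ids), name="total_mapped_reads"),
    )


@pytest.fixture
def toy_counts() -> CountMatrix:
    """Six genes, two equal-depth libraries; covers strong up/down, identical
    counts, zero-in-one-library and low-count cases."""
    counts = [[250, 1000], [100, 100], [80, 0], [11, 10], [2600, 5000], [0, 3]]
    return make_count_matrix(counts, [1000] * 6, [10**6, 10**6],
                             sample_ids=["ref", "trt"])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
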