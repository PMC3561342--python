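import numpy as np
import pandas as pd
import pytest

from hkatlas.core import ExpressionMatrix, SampleMeta
from hkatlas.simulate import SimConfig, simulate_expression, simulate_intergenic


def make_matrix(values, groups, gene_ids=None):
    """Small ExpressionMatrix from a 2-D list; groups like 'nnncc'."""
    arr = np.asarray(values, dtype=float)
    n_genes, n_samples = arr.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(1, n_genes + 1)]
    samples = []
    counters = {"n": 0, "c": 0}
    for ch in groups:
        counters[ch] += 1
        samples.append(SampleMeta(f"{ch.upper()}{counters[ch]}",
                                  "normal" if ch == "n" else "cancer", 10_000_000, 32))
    df = pd.DataFrame(arr, index=gene_ids, columns=[s.sample_id for s in samples])
    return ExpressionMatrix(df, samples)


@pytest.fixture(scope="session")
def small_study():
    """A modest planted study shared by recovery-flavoured tests."""
    cfg = SimConfig(n_genes=2000, seed=11)
    matrix, truth = simulate_expression(cfg)
    intergenic = simulate_intergenic(cfg, 2000)
    return cfg, matrix, truth, intergenic
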