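import numpy as np
import pandas as pd
import pytest

from methfert.matrix import MethCountMatrix
from methfert.synth import simulate_annotation


def make_matrix(meth, total, chrom="chr1", start=101, step=50, samples=None):
    """Small MethCountMatrix from dense count arrays (0 total = not covered)."""
    meth = np.atleast_2d(np.asarray(meth))
    total = np.atleast_2d(np.asarray(total))
    n_sites, n_samples = total.shape
    sites = pd.DataFrame({
        "chrom": [chrom] * n_sites,
        "pos": [start + i * step for i in range(n_sites)],
    })
    if samples is None:
        samples = [f"s{j + 1}" for j in range(n_samples)]
    return MethCountMatrix(sites=sites, samples=list(samples),
                           meth=meth, total=total, covered=total > 0)


def two_class_labels(matrix, n_fertile):
    labels = (["fertile"] * n_fertile
              + ["subfertile"] * (matrix.n_samples - n_fertile))
    return pd.Series(labels, index=matrix.samples)


@pytest.fixture(scope="session")
def toy_annotation():
    return simulate_annotation(n_genes=6, genome_length=1_000_000, seed=42)


@pytest.fixture
def matrix_factory():
    return make_matrix
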