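import numpy as np
import pandas as pd
import pytest

from methyldyn import SampleMethylome, SimConfig, simulate


def make_methylome(rows, sample_id="test"):
    """rows: iterable of (chrom, pos, strand, context, mc, cov)."""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "mc", "cov"])
    return SampleMethylome(sample_id, df)


@pytest.fixture
def tiny_methylome():
    return make_methylome([
        ("chr1", 100, "+", "CGT", 3, 10),
        ("chr1", 200, "+", "CAC", 1, 10),
        ("chr1", 300, "-", "CAT", 0, 5),
        ("chr1", 400, "+", "CGA", 5, 5),
        ("chr1", 500, "+", "CCG", 2, 4),
        ("chr2", 100, "+", "CGT", 0, 0),
    ])


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition synthetic dataset shared across the session."""
    return simulate(SimConfig(seed=42))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20241001)
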