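import numpy as np
import pytest

from epiloci.geno_qc import GenotypeMatrix, VariantRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_gm(calls, chrom="1", positions=None, ids=None, hidden=None):
    """Build a GenotypeMatrix from a 2-D array of calls (rows = individuals)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    positions = positions or [1000 * (j + 1) for j in range(m)]
    ids = ids or [f"rs{j + 1}" for j in range(m)]
    hidden = hidden or [False] * m
    variants = [
        VariantRecord(ids[j], chrom, positions[j], hidden=hidden[j]) for j in range(m)
    ]
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n)], variants=variants, calls=calls
    )


@pytest.fixture
def gm_builder():
    return make_gm
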