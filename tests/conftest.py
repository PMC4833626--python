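import numpy as np
import pandas as pd
import pytest

from selflines.genotypes import GenotypeMatrix


def make_matrix(calls, sites=None, groups=None, rad_ids=None, offsets=None):
    """Build a GenotypeMatrix from a plain call array with default metadata."""
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    ind = pd.DataFrame(
        {
            "id": [f"ind{i}" for i in range(n)],
            "site": sites if sites is not None else ["s0"] * n,
        }
    )
    if groups is not None:
        ind["group"] = groups
    loci = pd.DataFrame(
        {
            "rad_locus_id": rad_ids
            if rad_ids is not None
            else [f"RAD{j:04d}" for j in range(L)],
            "snp_offset": offsets if offsets is not None else [30] * L,
            "ref": ["A"] * L,
            "alt": ["T"] * L,
        }
    )
    return GenotypeMatrix(calls=calls, individuals=ind, loci=loci)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_group_matrix(rng):
    """Random two-group matrix: 10 individuals, 20 loci, some missing."""
    calls = rng.integers(0, 3, size=(10, 20)).astype(np.int8)
    miss = rng.random((10, 20)) < 0.1
    calls[miss] = -1
    groups = ["A"] * 5 + ["B"] * 5
    return make_matrix(calls, groups=groups)
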