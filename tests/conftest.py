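import numpy as np
import pytest

from msatdemog.genotypes import GenotypeMatrix, Locus


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_matrix(calls, groups=None, repeat_min=1, repeat_max=35, n_loci=None):
    """Small genotype matrix from a nested call list
    calls[individual][locus] = (a, b)."""
    calls = np.asarray(calls, dtype=np.int64)
    if calls.ndim == 2:
        calls = calls[:, None, :]
    n_ind, n_loci_, _ = calls.shape
    loci = [Locus(f"L{j + 1}", repeat_min=repeat_min, repeat_max=repeat_max)
            for j in range(n_loci_)]
    groups = groups or ["pop1"] * n_ind
    return GenotypeMatrix(
        ids=[f"ind{i + 1}" for i in range(n_ind)],
        groups=list(groups),
        loci=loci,
        calls=calls,
    )


@pytest.fixture
def two_locus_matrix():
    return make_matrix(
        [
            [(10, 12), (20, 20)],
            [(10, 10), (20, 22)],
            [(12, 12), (22, 22)],
            [(10, 12), (20, 22)],
        ]
    )
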