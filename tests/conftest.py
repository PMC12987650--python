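import numpy as np
import pytest

from lncevo.popgen import HaplotypePanel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_panel(rng, n=10, s=12, pop="CEU", unknown_frac=0.0):
    """A random biallelic panel; every site is polymorphic."""
    mat = np.zeros((n, s), dtype=np.int8)
    for j in range(s):
        c = int(rng.integers(1, n))
        mat[rng.choice(n, size=c, replace=False), j] = 1
    anc = np.zeros(s, dtype=np.int8)
    flip = rng.random(s) < 0.3
    anc[flip] = 1
    if unknown_frac:
        anc[rng.random(s) < unknown_frac] = -1
    return HaplotypePanel(matrix=mat, positions=np.arange(s) * 10,
                          ancestral=anc, population=pop)


@pytest.fixture
def small_panel(rng):
    return random_panel(rng)
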