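import numpy as np
import pytest

from rhepcg.core import StandardizedDesign, standardize


def random_dosages(n, m, rng):
    """Random polymorphic dosage matrix (no constant columns)."""
    while True:
        mat = rng.integers(0, 3, size=(n, m))
        if (mat.min(axis=0) != mat.max(axis=0)).all():
            return mat


def random_design(n, m, seed, with_y=True) -> StandardizedDesign:
    rng = np.random.default_rng(seed)
    mat = random_dosages(n, m, rng)
    y = rng.standard_normal(n) if with_y else None
    return standardize(mat, y)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_design():
    return random_design(20, 8, seed=7)
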