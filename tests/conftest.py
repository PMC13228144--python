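import numpy as np
import pytest

from selfkit.genotypes import GenotypeMatrix


def make_gm(geno, pops=None) -> GenotypeMatrix:
    """Wrap a plain array as a GenotypeMatrix with generated metadata."""
    geno = np.asarray(geno, dtype=np.int8)
    n, L = geno.shape
    return GenotypeMatrix(
        geno,
        [f"ind{i}" for i in range(n)],
        list(pops) if pops is not None else ["pop1"] * n,
        [f"L{j}" for j in range(L)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_gm(rng):
    """10 individuals x 50 loci with some missingness, two populations."""
    geno = rng.integers(0, 3, size=(10, 50)).astype(np.int8)
    geno[rng.random(geno.shape) < 0.1] = -1
    return make_gm(geno, pops=["A"] * 5 + ["B"] * 5)
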