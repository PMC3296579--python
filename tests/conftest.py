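import numpy as np
import pytest

from collapsar import GenotypeMatrix, PhenotypeVector


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_region(
    rng: np.random.Generator,
    n: int = 80,
    n_common: int = 3,
    n_rare: int = 8,
    common_p: float = 0.3,
    rare_p: float = 0.04,
) -> GenotypeMatrix:
    """A small random mixed region; rare/common split via a 0.15 threshold."""
    Xc = rng.binomial(2, common_p, (n, n_common))
    Xr = rng.binomial(2, rare_p, (n, n_rare))
    return GenotypeMatrix.from_values(
        np.hstack([Xc, Xr]), rare_threshold=0.15
    )


def random_phenotype(rng: np.random.Generator, n: int = 80) -> PhenotypeVector:
    y = rng.binomial(1, 0.5, n).astype(float)
    if y.sum() == 0:
        y[0] = 1.0
    if y.sum() == n:
        y[0] = 0.0
    return PhenotypeVector(y)


@pytest.fixture
def small_region(rng):
    return random_region(rng)


@pytest.fixture
def small_phenotype(rng):
    return random_phenotype(rng)
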