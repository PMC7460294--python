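from fractions import Fraction

import pytest

from genegames import (
    MicroarrayNetworkGame,
    apply_discriminant,
    similarity_matrix,
    threshold_network,
)
from genegames.datasets import five_gene_mes


@pytest.fixture(scope="session")
def mes5():
    """The bundled five-gene demonstration experimental situation."""
    return five_gene_mes()


@pytest.fixture(scope="session")
def disc5(mes5):
    return apply_discriminant(mes5)


@pytest.fixture(scope="session")
def sim5(disc5):
    return similarity_matrix(disc5)


@pytest.fixture(scope="session")
def net5(sim5):
    """tau = 0.8 co-expression network: links {12, 23, 45}."""
    return threshold_network(sim5, 0.8)


@pytest.fixture(scope="session")
def game5(net5):
    return MicroarrayNetworkGame(net5)


def frac(num, den=1):
    return Fraction(num, den)
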