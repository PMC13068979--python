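import numpy as np
import pytest

from latticefold.fold import InteractionMatrix, Sequence


@pytest.fixture(scope="session")
def hp():
    return InteractionMatrix.hp()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def flaw_sequence():
    return Sequence("HPPPPHPPPPH")


def random_hubo(rng, n_vars=6, n_terms=12, max_degree=4, coeff_range=5):
    """Random integer-coefficient HUBO used by the reduction tests."""
    from latticefold.polynomial import BinaryPolynomial

    poly = BinaryPolynomial()
    for _ in range(n_terms):
        k = int(rng.integers(1, max_degree + 1))
        mono = tuple(int(v) for v in rng.choice(n_vars, size=k, replace=False))
        coeff = int(rng.integers(-coeff_range, coeff_range + 1))
        if coeff:
            poly.add_term(mono, float(coeff))
    return poly
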