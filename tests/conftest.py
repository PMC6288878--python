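import numpy as np
import pytest

from edlogo import Alphabet, Background, ProbabilityMatrix, paper_fixtures

DNA = Alphabet(("A", "C", "G", "T"))


@pytest.fixture(scope="session")
def fixtures():
    return paper_fixtures()


@pytest.fixture
def uniform_bg():
    return Background.uniform()


def random_simplex(rng: np.random.Generator, n: int, floor: float = 1e-3) -> np.ndarray:
    """A strictly positive probability vector, bounded away from zero."""
    v = rng.dirichlet(np.ones(n)) + floor
    return v / v.sum()


def prob_matrix(vec) -> ProbabilityMatrix:
    vec = np.asarray(vec, dtype=float)
    alph = Alphabet(tuple("S%d" % i for i in range(vec.size))) if vec.size != 4 else DNA
    return ProbabilityMatrix([1], [alph], [vec])
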