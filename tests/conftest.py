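import numpy as np
import pytest

from aplkit import CplMatrix, ScoringModel, build_scoring_model


def random_scoring_model(rng: np.random.Generator) -> ScoringModel:
    """A random scoring model over a small universe (for oracle comparisons)."""
    length = int(rng.integers(1, 6))
    n_aa = int(rng.integers(2, 7))
    alphabet = tuple("ACDEFG"[:n_aa])
    response = rng.uniform(0.0, 10.0, size=(length, n_aa))
    response[rng.random(size=response.shape) < 0.2] = 0.0
    response[np.arange(length), rng.integers(0, n_aa, size=length)] += 1.0
    matrix = CplMatrix(length=length, alphabet=alphabet, response=response)
    return build_scoring_model(matrix, pseudocount=float(rng.uniform(1e-4, 1e-1)))


@pytest.fixture
def tie_model() -> ScoringModel:
    """Two-position model whose top two peptides ('AC', 'AD') tie exactly."""
    matrix = CplMatrix(
        length=2,
        alphabet=("A", "C", "D"),
        response=np.array([[0.9, 0.1, 0.0], [0.0, 0.5, 0.5]]),
    )
    return build_scoring_model(matrix, pseudocount=1e-12)
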