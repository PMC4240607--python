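import numpy as np
import pytest

from supergenome import GeneContentMatrix, make_reservoir


@pytest.fixture
def two_genome_matrix() -> GeneContentMatrix:
    """Genome1 carries {A, B}, genome2 carries {B, C}."""
    return GeneContentMatrix(
        genome_ids=("genome1", "genome2"),
        family_ids=("A", "B", "C"),
        counts=np.array([[1, 1, 0], [0, 2, 1]]),
    )


@pytest.fixture
def uniform_reservoir_small():
    return make_reservoir(100, "uniform")
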