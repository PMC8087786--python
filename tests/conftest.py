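import numpy as np
import pytest

from casaudit import Genome, generate_genome


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_genome():
    return generate_genome(2000, n_chromosomes=2, gc=0.4, seed=11)


@pytest.fixture
def flat_genome():
    """A fixed tiny genome for hand-computed examples."""
    return Genome(chroms={"chr1": "AAAACCCCGGGG"})
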