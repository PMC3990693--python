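import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make _oracles importable

from sagscope import make_genome


@pytest.fixture(scope="session")
def small_genome():
    """A 50 kbp archaeal-like (34% GC) genome shared across tests."""
    return make_genome(50_000, 0.34, seed=101)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_dna(rng, length):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
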