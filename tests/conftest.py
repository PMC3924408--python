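import numpy as np
import pytest

from plaspred.seqio import AMINO_ACIDS, ProteinSequence
from plaspred.synthetic import benchmark, default_profiles


def random_protein(rng: np.random.Generator, length: int,
                   seq_id: str = "rand") -> ProteinSequence:
    idx = rng.integers(0, 20, size=length)
    residues = "".join(AMINO_ACIDS[i] for i in idx)
    return ProteinSequence(id=seq_id, residues=residues)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_benchmark():
    """A scaled-down labelled dataset for model-level tests."""
    counts = {"SAK": 20, "SK": 40, "tPA": 8, "UK": 30, "NEG": 80}
    return benchmark(default_profiles(), counts, seed=11)
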