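import numpy as np
import pytest

from seqk import NucleotideSequence

LETTERS = np.array(list("ACGT"))


def random_residues(rng: np.random.Generator, length: int) -> str:
    return "".join(LETTERS[rng.integers(0, 4, length)])


def random_sequence(rng: np.random.Generator, length: int, id: str = "s") -> NucleotideSequence:
    return NucleotideSequence(id, random_residues(rng, length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240912)
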