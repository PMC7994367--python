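import numpy as np
import pytest

from sigsom.genome_io import GenomeRecord


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_dna(rng, length, alphabet="ACGT"):
    return "".join(np.asarray(list(alphabet))[rng.integers(0, len(alphabet), length)])


@pytest.fixture
def small_record(rng):
    return GenomeRecord("chr_t", "testspecies", random_dna(rng, 5000))
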