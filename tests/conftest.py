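import numpy as np
import pytest

from taxodelim.records import SeqRecord


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220328)


def random_protein(rng, length):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def toy_proteins(rng):
    return [SeqRecord(f"p{i}", random_protein(rng, 30)) for i in range(6)]
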