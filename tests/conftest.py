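import numpy as np
import pytest

from asmcurate.core import SeqRecord

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list(BASES))[rng.choice(4, size=n, p=p)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_contigs(rng):
    """Two contigs sharing one exact 300-bp segment, otherwise random."""
    shared = random_dna(rng, 300)
    a = random_dna(rng, 400) + shared + random_dna(rng, 300)
    b = random_dna(rng, 150) + shared + random_dna(rng, 550)
    return [SeqRecord("ctgA", a), SeqRecord("ctgB", b)], shared
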