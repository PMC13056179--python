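import random

import numpy as np
import pytest

from kmerstat.simulate import make_diploid, simulate_reads


def revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def random_dna(n: int, rng: random.Random) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture
def rng():
    return random.Random(1234)


@pytest.fixture
def np_rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_reads():
    """200 random 100 bp reads (no shared k-mers beyond chance)."""
    r = random.Random(7)
    return ["".join(r.choice("ACGT") for _ in range(100)) for _ in range(200)]


@pytest.fixture(scope="session")
def multiplicity_reads():
    """Reads with controlled k-mer multiplicities (duplicated templates)."""
    r = random.Random(11)
    templates = ["".join(r.choice("ACGT") for _ in range(80)) for _ in range(30)]
    reads = []
    for t in templates:
        reads.extend([t] * r.randint(1, 8))
    r.shuffle(reads)
    return reads


@pytest.fixture(scope="session")
def tiny_fixture():
    """Small diploid fixture: 100 kbp genome, 20x short reads, 0.5% errors."""
    genome = make_diploid(100_000, snv_rate=0.005, seed=42)
    reads = simulate_reads(genome, coverage=20, read_length=100, error_rate=0.005, seed=43)
    return genome, reads
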