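import numpy as np
import pytest

from trflpkit.synthetic import default_study, generate_community
from trflpkit.types import SequenceRecord


@pytest.fixture(scope="session")
def community():
    """One 30-taxon reference community shared by the slower tests."""
    return generate_community(seed=11)


@pytest.fixture(scope="session")
def study():
    """The default emulated study (two libraries + 15 x 2 profiles)."""
    return default_study(seed=7)


@pytest.fixture
def random_records():
    """Factory for random unaligned sequence records."""

    def make(n, length=120, seed=0, with_taxon=False):
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        out = []
        for i in range(n):
            seq = "".join(rng.choice(bases, size=length))
            taxon = f"Phylum{i % 3}/Class{i % 5}" if with_taxon else None
            out.append(SequenceRecord(f"r{i:03d}", seq, taxon=taxon))
        return out

    return make
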