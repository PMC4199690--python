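import numpy as np
import pytest

from cubscan.codon_core import AMINO_ACIDS, SYNONYMS
from cubscan.seq_io import CodingSequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def one_codon_per_aa_cds() -> str:
    """Every amino acid encoded by a single fixed synonym, three times each:
    the maximally biased full-coverage CDS (ENC lower bound)."""
    return "".join(SYNONYMS[aa][0] * 3 for aa in AMINO_ACIDS if aa != "*")


@pytest.fixture
def equal_usage_cds() -> str:
    """Every sense codon of every family used exactly four times: even
    synonymous usage (ENC upper bound after capping)."""
    return "".join(c * 4 for aa in AMINO_ACIDS if aa != "*" for c in SYNONYMS[aa])


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """A random CDS without stop codons."""
    sense = [c for aa in AMINO_ACIDS if aa != "*" for c in SYNONYMS[aa]]
    return "".join(rng.choice(sense, size=n_codons))


@pytest.fixture
def small_gene_set(rng) -> list[CodingSequence]:
    return [
        CodingSequence(f"g{i}", "test", random_cds(rng, int(rng.integers(20, 80))))
        for i in range(8)
    ]
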