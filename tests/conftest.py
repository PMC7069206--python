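import numpy as np
import pytest

from sketchtax.kmers import BuildParams
from sketchtax.sketch import h1_mix
from sketchtax.taxonomy import Taxonomy

BASES = "ACGT"


@pytest.fixture
def params():
    return BuildParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, length):
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture
def toy_taxonomy():
    """root(1) -> genus(10) -> species 100, 101; species 102 under root."""
    tax = Taxonomy()
    tax.add_node(1, 1, "root", "root")
    tax.add_node(10, 1, "genus", "genusA")
    tax.add_node(100, 10, "species", "speciesA")
    tax.add_node(101, 10, "species", "speciesB")
    tax.add_node(102, 1, "species", "speciesC")
    tax.validate()
    return tax


def find_prominent_kmer(rng, k=16, n_candidates=20_000):
    """A k-mer whose hash is small enough to enter any window's sketch."""
    best_seq, best_hash = None, None
    from sketchtax.kmers import canonical_kmer_code

    for _ in range(n_candidates):
        seq = random_dna(rng, k)
        try:
            h = h1_mix(canonical_kmer_code(seq))
        except ValueError:
            continue
        if best_hash is None or h < best_hash:
            best_seq, best_hash = seq, h
    return best_seq, best_hash
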