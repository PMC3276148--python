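import numpy as np
import pytest

from locuspair.alignment import Alignment


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_alignment(rng, n, L, p_poly=0.3, alphabet="ACGT"):
    """Random nucleotide alignment: each column monomorphic with prob
    1 - p_poly, otherwise a random mix of 2-3 bases."""
    bases = np.array(list(alphabet))
    seqs = np.empty((n, L), dtype="U1")
    for j in range(L):
        if rng.random() > p_poly:
            seqs[:, j] = rng.choice(bases)
        else:
            k = 2 if rng.random() < 0.9 else 3
            alleles = rng.choice(bases, size=k, replace=False)
            seqs[:, j] = rng.choice(alleles, size=n)
    ids = [f"s{i // 2:03d}|spp|hap{i % 2 + 1}" for i in range(n)]
    return Alignment(seqs, ids)


@pytest.fixture
def make_alignment(rng):
    def _make(n=10, L=50, p_poly=0.3):
        return random_alignment(rng, n, L, p_poly)

    return _make
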