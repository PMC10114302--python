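import numpy as np
import pytest

from ampbench.refs import PrimerSet, ReferenceSet
from ampbench.simulate import synthetic_reference_set

V4 = PrimerSet("V4-V4", "GTGYCAGCMGCCGCGGTAA", "GGACTACNVGGGTWTCTAAT", 254)

BASES = np.array(list("ACGT"))


def random_dna(rng, n):
    return "".join(BASES[rng.integers(0, 4, n)])


def mutate(seq, k, rng):
    """Substitute exactly k distinct positions, always to a different base."""
    s = list(seq)
    for p in rng.choice(len(s), size=k, replace=False):
        s[p] = rng.choice([b for b in "ACGT" if b != s[p]])
    return "".join(s)


@pytest.fixture(scope="session")
def primers_v4():
    return V4


@pytest.fixture(scope="session")
def mock37():
    """Default-scale community: 37 members, 23 expected V4 variants."""
    return synthetic_reference_set(seed=11)


@pytest.fixture(scope="session")
def mock_small():
    """Small, well-separated community for fast detector tests."""
    return synthetic_reference_set(n_members=8, n_variants=6, region_length=180,
                                   flank=120, seed=5)


def semiglobal_distance_oracle(read, ref):
    """Plain O(n*m) DP for infix edit distance; free gaps at reference ends."""
    n, m = len(read), len(ref)
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(prev[j - 1] + (read[i - 1] != ref[j - 1]),
                         prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return min(prev)
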