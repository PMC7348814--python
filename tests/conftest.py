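import numpy as np
import pytest

from orchardkit.genotypes import GenotypeTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)


def random_table(rng, n=10, loci=5, pops=("P1", "P2"), missing_rate=0.0) -> GenotypeTable:
    """Random diploid table with 2-4 alleles per locus (sizes 100+2k)."""
    n_alleles = rng.integers(2, 5, size=loci)
    calls = np.zeros((n, loci, 2), dtype=int)
    for l in range(loci):
        sizes = 100 + 10 * l + 2 * np.arange(n_alleles[l])
        calls[:, l, :] = rng.choice(sizes, size=(n, 2))
    missing = rng.random((n, loci)) < missing_rate
    pops_lab = [pops[i % len(pops)] for i in range(n)]
    return GenotypeTable(
        individuals=[f"I{i:02d}" for i in range(n)],
        loci=[f"L{l}" for l in range(loci)],
        populations=pops_lab,
        calls=calls,
        missing=missing,
    )


@pytest.fixture
def two_ind_table():
    """Two individuals, one locus: calls {180,184} and {180,180}."""
    return GenotypeTable(
        individuals=["a", "b"],
        loci=["L1"],
        populations=["P1", "P1"],
        calls=np.array([[[180, 184]], [[180, 180]]]),
    )
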