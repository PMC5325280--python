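import numpy as np
import pytest

from isopop.genotype import GenotypeTable, Locus


@pytest.fixture
def tiny_table() -> GenotypeTable:
    """Two individuals, one locus: genotypes 100/100 and 100/102."""
    calls = np.array([[[100, 100]], [[100, 102]]])
    return GenotypeTable(["a", "b"], ["pop1", "pop1"], [Locus("L1", 2)], calls)


@pytest.fixture
def two_pop_table() -> GenotypeTable:
    """Two fixed-difference populations at one locus plus a shared locus."""
    calls = np.array(
        [
            [[100, 100], [200, 202]],
            [[100, 100], [200, 200]],
            [[102, 102], [200, 202]],
            [[102, 102], [202, 202]],
        ]
    )
    return GenotypeTable(
        ["a1", "a2", "b1", "b2"],
        ["A", "A", "B", "B"],
        [Locus("L1", 2), Locus("L2", 2)],
        calls,
    )


def random_table(
    rng: np.random.Generator,
    n_individuals: int = 8,
    n_loci: int = 3,
    n_pops: int = 2,
    missing_rate: float = 0.1,
) -> GenotypeTable:
    """A small random diploid table for oracle-equivalence checks."""
    sizes = 100 + 2 * np.arange(4)
    calls = rng.choice(sizes, size=(n_individuals, n_loci, 2))
    miss = rng.random((n_individuals, n_loci)) < missing_rate
    calls[miss] = 0
    pops = [f"p{1 + (i % n_pops)}" for i in range(n_individuals)]
    # ensure every population has at least one fully genotyped individual
    for p in range(n_pops):
        calls[p] = rng.choice(sizes, size=(n_loci, 2))
    loci = [Locus(f"L{j}", 2) for j in range(n_loci)]
    return GenotypeTable(
        [f"i{i}" for i in range(n_individuals)], pops, loci, calls
    )
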