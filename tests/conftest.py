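import numpy as np
import pytest

from walnutkit.io_windows import GenotypeMatrix


@pytest.fixture
def tiny_matrix():
    """4 diploids in 2 populations, 3 sites on one 300-kb chromosome."""
    return GenotypeMatrix(
        chroms=np.asarray(["Chr1"] * 3, dtype=object),
        positions=np.asarray([5, 150_050, 150_060]),
        calls=np.asarray(
            [[0, 1, 2, 1], [1, 1, 0, 2], [0, 0, 1, 1]], dtype=np.int8
        ),
        samples=["a1", "a2", "b1", "b2"],
        groups={"a1": "popA", "a2": "popA", "b1": "popB", "b2": "popB"},
        chrom_lengths={"Chr1": 300_000},
    )


def brute_force_pi_sum(calls: np.ndarray) -> float:
    """Mean pairwise haplotype difference summed over sites, by enumeration.

    Each diploid contributes two chromosomes (dosage 1 -> one ref + one alt
    allele); missing calls contribute no chromosomes at that site.
    """
    total = 0.0
    for row in calls:
        alleles = []
        for d in row:
            if d == -1:
                continue
            alleles += [0, 0] if d == 0 else ([0, 1] if d == 1 else [1, 1])
        k = len(alleles)
        if k < 2:
            continue
        diff = sum(
            1
            for i in range(k)
            for j in range(i + 1, k)
            if alleles[i] != alleles[j]
        )
        total += diff / (k * (k - 1) / 2)
    return total
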