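from __future__ import annotations

import numpy as np
import pytest

from haplothread.core import AlleleMatrix, Read, Variant


def matrix_from_strings(rows: list[str], ploidy: int = 2,
                        genotypes=None) -> AlleleMatrix:
    """Build an allele matrix from rows like '01-0' ('-' = not covered)."""
    n = max(len(r) for r in rows)
    reads = []
    for ridx, row in enumerate(rows):
        positions = [i for i, ch in enumerate(row) if ch in "01"]
        alleles = [int(row[i]) for i in positions]
        reads.append(
            Read(id=f"r{ridx}", positions=np.array(positions),
                 alleles=np.array(alleles))
        )
    if genotypes is None:
        genotypes = [None] * n
    variants = [Variant(position=i + 1, index=i, genotype=genotypes[i])
                for i in range(n)]
    return AlleleMatrix(variants=variants, reads=reads, ploidy=ploidy)


@pytest.fixture
def small_matrix() -> AlleleMatrix:
    return matrix_from_strings(
        ["0101", "01-1", "-010", "1010"], ploidy=2, genotypes=[2, 2, 2, 2]
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
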