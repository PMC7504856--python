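"""Genotype verification and read-to-haplotype assignment.

Re-genotyping compares the observed fraction of alternative alleles at a
variant with the fractions expected under every possible polyploid genotype
(g/k for g = 0..k) and picks the closest; variants whose recomputed
genotype disagrees with the input call are dropped before phasing, as are
positions that re-genotype as homozygous.  Haplotagging assigns each read
to the phased haplotype it matches best, which enables per-haplotype read
splitting for downstream local assembly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import GAP, AlleleMatrix, Phasing, Read

logger = logging.getLogger(__name__)

UNTAGGED = -1


@dataclass(frozen=True)
class GenotypeCall:
    genotype: int | None          # alt-allele count in 0..k, None if no coverage
    alt_fraction: float | None    # observed fraction of alternative alleles
    distance: float               # |observed - expected| for the chosen genotype


def regenotype(matrix: AlleleMatrix, position: int,
               ploidy: int | None = None,
               method: str = "fraction") -> GenotypeCall:
    """Re-genotype one variant from the reads covering it.

    ``method="fraction"`` minimizes |alt_fraction - g/k| (ties toward the
    smaller genotype); ``method="binomial"`` maximizes the binomial
    likelihood of the observed alt count under rate g/k (clamped away from
    0/1), an alternative that weighs coverage depth.
    """
    k = ploidy or matrix.ploidy
    n_alt = 0
    n_cov = 0
    for r in matrix.reads:
        a = r.allele_at(position)
        if a != GAP:
            n_cov += 1
            n_alt += a
    if n_cov == 0:
        return GenotypeCall(genotype=None, alt_fraction=None, distance=np.inf)
    frac = n_alt / n_cov
    if method == "fraction":
        dists = [abs(frac - g / k) for g in range(k + 1)]
        g_star = int(np.argmin(dists))  # argmin takes the first = smallest g
        return GenotypeCall(genotype=g_star, alt_fraction=frac,
                            distance=dists[g_star])
    if method == "binomial":
        eps = 1e-6
        rates = np.clip(np.arange(k + 1) / k, eps, 1 - eps)
        ll = n_alt * np.log(rates) + (n_cov - n_alt) * np.log(1 - rates)
        g_star = int(np.argmax(ll))
        return GenotypeCall(genotype=g_star, alt_fraction=frac,
                            distance=abs(frac - g_star / k))
    raise ValueError(f"unknown re-genotyping method {method!r}")


def verify_genotypes(matrix: AlleleMatrix,
                     genotypes=None,
                     ploidy: int | None = None,
                     method: str = "fraction") -> np.ndarray:
    """Boolean mask of variants kept after genotype verification.

    A variant is kept iff its recomputed genotype equals the input call and
    is heterozygous (homozygous positions carry no phase information).
    """
    k = ploidy or matrix.ploidy
    if genotypes is None:
        genotypes = matrix.genotypes
    keep = np.zeros(matrix.n_variants, dtype=bool)
    for i in range(matrix.n_variants):
        g_in = genotypes[i]
        if g_in is None:
            continue
        call = regenotype(matrix, i, k, method=method)
        keep[i] = (
            call.genotype == int(g_in) and 0 < call.genotype < k
        )
    logger.info("genotype verification kept %d / %d variants",
                int(keep.sum()), matrix.n_variants)
    return keep


def haplotag(read: Read, phasing: Phasing) -> int:
    """Assign a read to the most similar phased haplotype.

    The read is compared within the phase block covering most of its
    variants (earliest block on ties); the haplotype with the most matching
    alleles wins, and ambiguity (no unique maximizer, e.g. in a collapsed
    stretch) or no overlap with phased variants yields UNTAGGED.
    """
    ps = phasing.phase_set[read.positions]
    covered = ps != GAP
    if not covered.any():
        return UNTAGGED
    blocks, counts = np.unique(ps[covered], return_counts=True)
    block = int(blocks[np.argmax(counts)])
    in_block = read.positions[covered & (ps == block)]
    alleles = read.alleles[covered & (ps == block)]
    hap = phasing.haplotypes[:, in_block]
    matches = np.sum((hap == alleles[None, :]) & (hap != GAP), axis=1)
    best = int(np.max(matches))
    winners = np.flatnonzero(matches == best)
    if len(winners) != 1:
        return UNTAGGED
    return int(winners[0])


def split_reads(matrix: AlleleMatrix, tags) -> tuple[list[list[Read]], list[Read]]:
    """Partition reads by haplotype tag; returns (k read lists, untagged)."""
    k = matrix.ploidy
    by_hap: list[list[Read]] = [[] for _ in range(k)]
    untagged: list[Read] = []
    for read, tag in zip(matrix.reads, tags):
        if tag == UNTAGGED:
            untagged.append(read)
        else:
            by_hap[int(tag)].append(read)
    logger.info("split reads: %s tagged per haplotype, %d untagged",
                [len(b) for b in by_hap], len(untagged))
    return by_hap, untagged


def tag_all_reads(matrix: AlleleMatrix, phasing: Phasing) -> np.ndarray:
    """Haplotag every read of the matrix (UNTAGGED for ambiguous reads)."""
    return np.array([haplotag(r, phasing) for r in matrix.reads], dtype=np.int64)


def write_tag_table(matrix: AlleleMatrix, phasing: Phasing, tags, path) -> None:
    """TSV per-read tag table: read_id, block_id, haplotype (or 'none')."""
    with open(path, "w") as fh:
        fh.write("# read_id\tblock_id\thaplotype\n")
        for read, tag in zip(matrix.reads, tags):
            ps = phasing.phase_set[read.positions]
            covered = ps[ps != GAP]
            if covered.size:
                blocks, counts = np.unique(covered, return_counts=True)
                block = str(int(blocks[np.argmax(counts)]))
            else:
                block = "none"
            hap = "none" if tag == UNTAGGED else str(int(tag))
            fh.write(f"{read.id}\t{block}\t{hap}\n")
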