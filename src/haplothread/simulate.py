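"""Seeded synthetic data: polyploid truth haplotypes and noisy long reads.

The generator emulates the situation a polyploid phaser faces after variant
calling: ``k`` haplotypes over ``n`` biallelic heterozygous SNVs, long reads
of known haplotype origin covering a contiguous stretch of variants, and a
per-allele error rate.  Collapsing regions -- stretches where two or more
haplotypes are identical -- can be planted explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GAP, AlleleMatrix, Read, Variant


@dataclass(frozen=True)
class CollapseSpec:
    """Plant an identical stretch: copy haplotype ``source`` onto ``target``
    over variant columns [start, start + length)."""

    source: int
    target: int
    start: int
    length: int = 50


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    ``difference_rate`` is the target pairwise Hamming rate between distinct
    haplotypes (must be <= 0.5 for the symmetric allele model used here).
    ``coverage`` is the mean number of reads per variant, ``mean_read_span``
    the mean number of variants covered per read, ``error_rate`` the
    probability of flipping each observed allele, and ``dropout_rate`` the
    probability of masking an allele inside a read's span.
    """

    ploidy: int = 4
    n_variants: int = 2000
    difference_rate: float = 0.4
    collapses: list[CollapseSpec] = field(default_factory=list)
    coverage: float = 40.0
    mean_read_span: float = 20.0
    error_rate: float = 0.05
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.difference_rate <= 0.5:
            raise ValueError("difference_rate must be in (0, 0.5]")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.mean_read_span < 2:
            raise ValueError("mean_read_span must be >= 2")
        for c in self.collapses:
            if not (0 <= c.start and c.start + c.length <= self.n_variants):
                raise ValueError("collapse interval outside [0, n)")
            if c.source == c.target:
                raise ValueError("collapse needs two distinct haplotypes")
            if not (0 <= c.source < self.ploidy and 0 <= c.target < self.ploidy):
                raise ValueError("collapse haplotype outside ploidy range")


def simulate_truth(cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Draw ground-truth haplotypes and derive genotypes.

    Alleles are i.i.d. Bernoulli(q) with q chosen so that the unconditional
    pairwise difference rate 2q(1-q) equals ``cfg.difference_rate``; columns
    that come out homozygous are resampled, so every variant is heterozygous.
    Collapses are enforced by copying, then re-checking heterozygosity.
    Genotypes are the column sums of the haplotype matrix.
    """
    rng = np.random.default_rng(cfg.seed)
    k, n, d = cfg.ploidy, cfg.n_variants, cfg.difference_rate
    q = (1.0 - np.sqrt(1.0 - 2.0 * d)) / 2.0

    if cfg.collapses and k == 2:
        raise ValueError("cannot plant a collapse at k=2 and stay heterozygous")

    hap = (rng.random((k, n)) < q).astype(np.int8)
    for _ in range(1000):
        for c in cfg.collapses:
            hap[c.target, c.start : c.start + c.length] = hap[
                c.source, c.start : c.start + c.length
            ]
        sums = hap.sum(axis=0)
        bad = np.flatnonzero((sums == 0) | (sums == k))
        if bad.size == 0:
            break
        hap[:, bad] = (rng.random((k, bad.size)) < q).astype(np.int8)
    else:
        raise ValueError("could not make all variant columns heterozygous")

    genotypes = hap.sum(axis=0).astype(np.int64)
    return hap, genotypes


def simulate_reads(haplotypes: np.ndarray, cfg: SimulationConfig) -> AlleleMatrix:
    """Draw noisy reads of known origin from the truth haplotypes.

    Reads start uniformly over the variant columns, span a geometric number
    of variants around the configured mean (minimum 2, truncated at the end
    of the region), originate from a uniformly chosen haplotype, and each
    observed allele is flipped independently with the error rate.  Alleles
    can additionally drop out ("-") inside the span.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    k, n = haplotypes.shape
    m = int(round(cfg.coverage * n / cfg.mean_read_span))
    starts = rng.integers(0, n, size=m)
    # geometric with mean = span - 1 extra variants beyond the first two
    extra_mean = max(cfg.mean_read_span - 2.0, 1e-9)
    extras = rng.geometric(1.0 / (1.0 + extra_mean), size=m) - 1
    lengths = np.minimum(2 + extras, n - starts)
    origins = rng.integers(0, k, size=m)

    reads = []
    width = len(str(m - 1)) if m else 1
    for idx in range(m):
        s, ln, h = int(starts[idx]), int(lengths[idx]), int(origins[idx])
        cols = np.arange(s, s + ln)
        alleles = haplotypes[h, s : s + ln].astype(np.int8)
        flips = rng.random(ln) < cfg.error_rate
        alleles = np.where(flips, 1 - alleles, alleles).astype(np.int8)
        if cfg.dropout_rate > 0:
            keep = rng.random(ln) >= cfg.dropout_rate
            if not keep.any():
                keep[rng.integers(0, ln)] = True
            cols, alleles = cols[keep], alleles[keep]
        reads.append(
            Read(id=f"sim{idx:0{width}d}", positions=cols, alleles=alleles,
                 true_haplotype=h)
        )

    genotypes = haplotypes.sum(axis=0)
    variants = [
        Variant(position=i + 1, index=i, genotype=int(genotypes[i]))
        for i in range(n)
    ]
    return AlleleMatrix(variants=variants, reads=reads, ploidy=k)


def simulate_dataset(cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray, AlleleMatrix]:
    """Convenience wrapper: (haplotypes, genotypes, allele matrix)."""
    hap, gt = simulate_truth(cfg)
    return hap, gt, simulate_reads(hap, cfg)


def write_truth_haplotypes(haplotypes: np.ndarray, path) -> None:
    """Write truth haplotypes as TSV: variant_index, then one column per
    haplotype (GAP rendered as '-')."""
    k, n = haplotypes.shape
    with open(path, "w") as fh:
        fh.write("# variant_index\t" + "\t".join(f"hap{t}" for t in range(k)) + "\n")
        for i in range(n):
            row = "\t".join(
                "-" if haplotypes[t, i] == GAP else str(int(haplotypes[t, i]))
                for t in range(k)
            )
            fh.write(f"{i}\t{row}\n")


def read_truth_haplotypes(path) -> np.ndarray:
    """Read the TSV haplotype table written by :func:`write_truth_haplotypes`."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            rows.append([GAP if p == "-" else int(p) for p in parts[1:]])
    return np.array(rows, dtype=np.int8).T
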