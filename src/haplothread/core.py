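"""Allele-matrix data model and I/O.

The central container is the :class:`AlleleMatrix`: ``m`` sequencing reads
observed at ``n`` biallelic heterozygous SNVs, each observation an allele in
``{0, 1}`` (0 = major/reference, 1 = minor/alternative).  Variants a read does
not cover are implicit ("-").  All downstream stages (pair scoring, cluster
editing, threading, evaluation) operate on this matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

#: allele code used for "variant not covered / unphased"
GAP = -1

MISSING_GENOTYPE = None


class MatrixFormatError(ValueError):
    """Raised for malformed allele-matrix input."""


@dataclass
class Variant:
    """One biallelic SNV column of the matrix.

    ``index`` is the 0-based column index; ``position`` the (1-based) genomic
    coordinate when the variant came from a VCF, otherwise a synthetic
    coordinate.  ``genotype`` is the number of alternative alleles among the
    ``k`` haplotypes, or ``None`` when unknown.
    """

    position: int
    index: int
    ref_allele: str = "A"
    alt_allele: str = "T"
    genotype: int | None = None
    chrom: str = "ref"


@dataclass
class Read:
    """A read's allele observations, sparse over variant columns.

    ``positions`` are sorted variant indices; ``alleles[i]`` is the allele
    (0/1) observed at ``positions[i]``.  ``true_haplotype`` is only set by the
    simulator and never used by the phasing itself.
    """

    id: str
    positions: np.ndarray
    alleles: np.ndarray
    true_haplotype: int | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.positions.size != self.alleles.size:
            raise ValueError("positions/alleles length mismatch")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            order = np.argsort(self.positions, kind="stable")
            self.positions = self.positions[order]
            self.alleles = self.alleles[order]
            if np.any(np.diff(self.positions) == 0):
                raise MatrixFormatError(
                    f"read {self.id!r}: duplicate variant observation"
                )

    @property
    def allele_map(self) -> dict[int, int]:
        return dict(zip(self.positions.tolist(), self.alleles.tolist()))

    def allele_at(self, index: int) -> int:
        """Allele at a variant column, or GAP if not covered."""
        i = np.searchsorted(self.positions, index)
        if i < len(self.positions) and self.positions[i] == index:
            return int(self.alleles[i])
        return GAP

    def __len__(self) -> int:
        return int(self.positions.size)


@dataclass
class AlleleMatrix:
    """Sparse reads-by-variants allele matrix for a ploidy-``k`` sample."""

    variants: list[Variant]
    reads: list[Read]
    ploidy: int = 2

    def __post_init__(self) -> None:
        if self.ploidy < 2:
            raise ValueError("ploidy must be >= 2")
        n = len(self.variants)
        for r in self.reads:
            if len(r) == 0:
                raise MatrixFormatError(f"read {r.id!r} covers no variant")
            if r.positions[0] < 0 or r.positions[-1] >= n:
                raise MatrixFormatError(
                    f"read {r.id!r} indexes a variant outside [0, {n})"
                )

    @property
    def n_reads(self) -> int:
        return len(self.reads)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def genotypes(self) -> list[int | None]:
        return [v.genotype for v in self.variants]

    def coverage_matrix(self) -> sparse.csr_matrix:
        """0/1 CSR matrix of shape (m, n): read covers variant."""
        indptr = np.cumsum([0] + [len(r) for r in self.reads])
        indices = (
            np.concatenate([r.positions for r in self.reads])
            if self.reads
            else np.empty(0, dtype=np.int64)
        )
        data = np.ones(len(indices), dtype=np.int32)
        return sparse.csr_matrix(
            (data, indices, indptr), shape=(self.n_reads, self.n_variants)
        )

    def signed_matrix(self) -> sparse.csr_matrix:
        """CSR matrix with +1 for allele 0 and -1 for allele 1."""
        indptr = np.cumsum([0] + [len(r) for r in self.reads])
        indices = (
            np.concatenate([r.positions for r in self.reads])
            if self.reads
            else np.empty(0, dtype=np.int64)
        )
        data = (
            1 - 2 * np.concatenate([r.alleles for r in self.reads]).astype(np.int32)
            if self.reads
            else np.empty(0, dtype=np.int32)
        )
        return sparse.csr_matrix(
            (data, indices, indptr), shape=(self.n_reads, self.n_variants)
        )

    def mean_read_span(self) -> float:
        """Mean number of variants covered per read."""
        if not self.reads:
            return 1.0
        return float(np.mean([len(r) for r in self.reads]))


@dataclass
class Phasing:
    """``k`` phased haplotype sequences plus phase-block identifiers.

    ``haplotypes`` is a (k, n) int8 array over {0, 1, GAP}.  ``phase_set`` is
    the per-variant block id (index of the first variant of the block), or
    GAP where the variant is unphased; all haplotypes share unphased
    positions.  ``haplo_phase_set`` is the finer per-haplotype block id (a
    haplotype keeps its block across a cut it was not involved in).
    """

    haplotypes: np.ndarray
    phase_set: np.ndarray
    haplo_phase_set: np.ndarray
    variants: list[Variant] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.phase_set = np.asarray(self.phase_set, dtype=np.int64)
        self.haplo_phase_set = np.asarray(self.haplo_phase_set, dtype=np.int64)
        k, n = self.haplotypes.shape
        if self.phase_set.shape != (n,) or self.haplo_phase_set.shape != (k, n):
            raise ValueError("inconsistent phasing shapes")
        unphased = self.phase_set == GAP
        if np.any(self.haplotypes[:, ~unphased] == GAP):
            # within one phase set no haplotype may be a gap
            raise ValueError("gap allele at a phased position")

    @property
    def ploidy(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    def blocks(self) -> list[np.ndarray]:
        """Phased variant indices grouped by phase set, in genome order."""
        out: dict[int, list[int]] = {}
        for j, ps in enumerate(self.phase_set.tolist()):
            if ps != GAP:
                out.setdefault(ps, []).append(j)
        return [np.array(out[ps]) for ps in sorted(out)]


# ---------------------------------------------------------------------------
# pairwise read statistics


def overlap(r: Read, s: Read) -> int:
    """Number of variants covered by both reads."""
    return int(np.intersect1d(r.positions, s.positions, assume_unique=True).size)


def disagreements(r: Read, s: Read) -> int:
    """Number of shared variants at which the two reads disagree."""
    common, ri, si = np.intersect1d(
        r.positions, s.positions, assume_unique=True, return_indices=True
    )
    return int(np.sum(r.alleles[ri] != s.alleles[si]))


def read_hamming_rate(r: Read, s: Read) -> float:
    """Fraction of shared variants with disagreeing alleles (dis / olp)."""
    olp = overlap(r, s)
    if olp == 0:
        raise ValueError("Hamming rate undefined for non-overlapping reads")
    return disagreements(r, s) / olp


# ---------------------------------------------------------------------------
# TSV allele-matrix format: read_id <TAB> variant_index <TAB> allele


def read_allele_matrix(
    path,
    ploidy: int = 2,
    n_variants: int | None = None,
    genotypes: list[int | None] | None = None,
) -> AlleleMatrix:
    """Read the native TSV allele-matrix format.

    Columns are read id, 0-based variant index and allele (0/1); lines
    starting with '#' are comments.  Reads covering no variant cannot be
    represented and a duplicated (read, variant) pair with conflicting
    alleles is an error.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=["read_id", "variant_index", "allele"],
            dtype={"read_id": str},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise MatrixFormatError(f"cannot parse allele matrix {path}: {exc}") from exc
    for col in ("variant_index", "allele"):
        if not np.issubdtype(df[col].dtype, np.integer):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
            line = bad.index[0] + 1 if len(bad) else "?"
            raise MatrixFormatError(f"{path}: non-integer {col} near record {line}")
    if not df["allele"].isin([0, 1]).all():
        bad = df.index[~df["allele"].isin([0, 1])][0] + 1
        raise MatrixFormatError(f"{path}: allele outside {{0,1}} at record {bad}")
    dup = df.duplicated(subset=["read_id", "variant_index"], keep=False)
    if dup.any():
        confl = (
            df[dup].groupby(["read_id", "variant_index"])["allele"].nunique() > 1
        )
        if confl.any():
            rid, vidx = confl.idxmax()
            raise MatrixFormatError(
                f"{path}: conflicting alleles for read {rid!r} at variant {vidx}"
            )
        df = df.drop_duplicates(subset=["read_id", "variant_index"])

    n = int(df["variant_index"].max()) + 1 if len(df) else 0
    if n_variants is not None:
        if n > n_variants:
            raise MatrixFormatError(
                f"{path}: variant index {n - 1} exceeds declared n={n_variants}"
            )
        n = n_variants
    reads = []
    for rid, grp in df.groupby("read_id", sort=True):
        reads.append(
            Read(
                id=str(rid),
                positions=grp["variant_index"].to_numpy(),
                alleles=grp["allele"].to_numpy(),
            )
        )
    if genotypes is None:
        genotypes = [None] * n
    variants = [
        Variant(position=i + 1, index=i, genotype=genotypes[i]) for i in range(n)
    ]
    return AlleleMatrix(variants=variants, reads=reads, ploidy=ploidy)


def write_allele_matrix(matrix: AlleleMatrix, path) -> None:
    """Write the TSV allele-matrix format (deterministic row order)."""
    with open(path, "w") as fh:
        fh.write("# read_id\tvariant_index\tallele\n")
        for r in matrix.reads:
            for pos, al in zip(r.positions.tolist(), r.alleles.tolist()):
                fh.write(f"{r.id}\t{pos}\t{al}\n")


# ---------------------------------------------------------------------------
# BAM + VCF ingestion


def matrix_from_bam(
    bam_path,
    vcf_path,
    ploidy: int,
    sample: str | None = None,
    chromosome: str | None = None,
) -> AlleleMatrix:
    """Build an allele matrix from an alignment file and a variant file.

    Only biallelic SNVs with a heterozygous genotype enter the matrix.  For
    each read spanning a variant, the aligned base is compared against the
    REF/ALT alleles; bases matching neither count as not covered.  Reads
    covering no heterozygous variant are dropped (count logged).
    """
    import pysam

    variants = read_vcf_variants(vcf_path, ploidy=ploidy, sample=sample,
                                 chromosome=chromosome)
    if not variants:
        raise MatrixFormatError(f"{vcf_path}: no usable biallelic SNVs")
    chrom = variants[0].chrom
    pos_to_col = {v.position: v.index for v in variants}

    observations: dict[str, dict[int, int]] = {}
    dropped = 0
    with pysam.AlignmentFile(str(bam_path)) as bam:
        try:
            alignments = list(bam.fetch(chrom, multiple_iterators=False))
        except ValueError:  # no index (e.g. SAM input): scan everything
            alignments = [a for a in bam if a.reference_name == chrom]
        for aln in alignments:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            seq = aln.query_sequence
            if seq is None:
                continue
            obs = observations.setdefault(aln.query_name, {})
            for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                col = pos_to_col.get(rpos + 1)  # VCF positions are 1-based
                if col is None:
                    continue
                base = seq[qpos].upper()
                v = variants[col]
                if base == v.ref_allele:
                    obs[col] = 0
                elif base == v.alt_allele:
                    obs[col] = 1
    reads = []
    for rid in sorted(observations):
        obs = observations[rid]
        if not obs:
            dropped += 1
            continue
        cols = np.array(sorted(obs), dtype=np.int64)
        reads.append(Read(id=rid, positions=cols,
                          alleles=np.array([obs[c] for c in cols])))
    if dropped:
        logger.info("dropped %d reads covering no heterozygous variant", dropped)
    return AlleleMatrix(variants=variants, reads=reads, ploidy=ploidy)


def read_vcf_variants(
    vcf_path,
    ploidy: int,
    sample: str | None = None,
    chromosome: str | None = None,
) -> list[Variant]:
    """Load biallelic heterozygous SNVs (with polyploid GT) from a VCF."""
    import pysam

    variants: list[Variant] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        samples = list(vcf.header.samples)
        if sample is None:
            if not samples:
                raise MatrixFormatError(f"{vcf_path}: no sample column")
            sample = samples[0]
        for rec in vcf:
            if chromosome is not None and rec.chrom != chromosome:
                continue
            if rec.alts is None or len(rec.alts) != 1:
                continue  # multiallelic or missing ALT
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                continue  # indel / MNP
            gt = rec.samples[sample].get("GT")
            if gt is None or any(a is None for a in gt):
                genotype = None
            else:
                if len(gt) != ploidy:
                    raise MatrixFormatError(
                        f"{vcf_path}: genotype arity {len(gt)} != ploidy {ploidy} "
                        f"at {rec.chrom}:{rec.pos}"
                    )
                genotype = int(sum(gt))
                if genotype == 0 or genotype == ploidy:
                    continue  # homozygous: not a phasing target
            variants.append(
                Variant(
                    position=rec.pos,
                    index=len(variants),
                    ref_allele=rec.ref,
                    alt_allele=rec.alts[0],
                    genotype=genotype,
                    chrom=rec.chrom,
                )
            )
    return variants
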