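"""Phased VCF output and input (GT / PS / HS FORMAT fields).

The phasing is emitted in the conventional way: a pipe-separated ploidy-k GT
per variant, a PS phase-set identifier (the genomic position of the first
variant of the block), and a custom HS field with one block identifier per
haplotype -- haplotypes not involved in a cut keep their HS block across it,
so HS blocks can be longer than PS blocks.
"""

from __future__ import annotations

import logging

import numpy as np
import pysam

from .core import GAP, Phasing, Variant

logger = logging.getLogger(__name__)


def _make_header(variants: list[Variant], ploidy: int,
                 sample: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    chrom = variants[0].chrom if variants else "ref"
    length = max(v.position for v in variants) + 1 if variants else 1
    header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("PS", 1, "Integer", "Phase set identifier")
    header.formats.add(
        "HS", ".", "Integer",
        f"Per-haplotype phase set identifiers ({ploidy} values)",
    )
    header.add_sample(sample)
    return header


def write_phased_vcf(phasing: Phasing, path, sample: str = "sample") -> None:
    """Write a phasing as a VCF with GT, PS and HS FORMAT fields."""
    variants = phasing.variants
    if not variants:
        raise ValueError("phasing carries no variant records")
    k = phasing.ploidy
    header = _make_header(variants, k, sample)
    pos_of = [v.position for v in variants]
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, v in enumerate(variants):
            rec = out.new_record(
                contig=v.chrom,
                start=v.position - 1,
                stop=v.position,
                alleles=(v.ref_allele, v.alt_allele),
            )
            rec.id = "."
            rec.qual = None
            s = rec.samples[sample]
            if phasing.phase_set[j] != GAP:
                s["GT"] = tuple(int(a) for a in phasing.haplotypes[:, j])
                s.phased = True
                s["PS"] = int(pos_of[int(phasing.phase_set[j])])
                s["HS"] = [
                    int(pos_of[int(h)]) for h in phasing.haplo_phase_set[:, j]
                ]
            else:
                g = v.genotype
                if g is None:
                    s["GT"] = (None,) * k
                else:
                    s["GT"] = tuple(sorted([1] * int(g) + [0] * (k - int(g))))
                s.phased = False
            out.write(rec)


def read_phased_vcf(path, ploidy: int | None = None,
                    sample: str | None = None) -> Phasing:
    """Read a phased VCF (as written by :func:`write_phased_vcf`)."""
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if sample is None:
            sample = samples[0]
        for rec in vcf:
            records.append(
                (
                    rec.chrom,
                    rec.pos,
                    rec.ref,
                    rec.alts[0] if rec.alts else "N",
                    rec.samples[sample].get("GT"),
                    rec.samples[sample].phased,
                    rec.samples[sample].get("PS"),
                    rec.samples[sample].get("HS"),
                )
            )
    n = len(records)
    if n == 0:
        raise ValueError(f"{path}: empty VCF")
    if ploidy is None:
        ploidy = len(records[0][4])
    k = ploidy
    idx_of_pos = {pos: j for j, (_, pos, *_rest) in enumerate(records)}

    variants = []
    haplotypes = np.full((k, n), GAP, dtype=np.int8)
    phase_set = np.full(n, GAP, dtype=np.int64)
    haplo_ps = np.full((k, n), GAP, dtype=np.int64)
    for j, (chrom, pos, ref, alt, gt, phased, ps, hs) in enumerate(records):
        genotype = None if gt is None or any(a is None for a in gt) else int(sum(gt))
        variants.append(
            Variant(position=pos, index=j, ref_allele=ref, alt_allele=alt,
                    genotype=genotype, chrom=chrom)
        )
        if phased and ps is not None:
            haplotypes[:, j] = list(gt)
            phase_set[j] = idx_of_pos[int(ps)]
            if hs is not None:
                haplo_ps[:, j] = [idx_of_pos[int(h)] for h in hs]
    return Phasing(haplotypes=haplotypes, phase_set=phase_set,
                   haplo_phase_set=haplo_ps, variants=variants)
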