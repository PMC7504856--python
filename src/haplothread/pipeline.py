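"""End-to-end phasing pipeline: scoring -> clustering -> threading -> blocks."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import blocks as blocks_mod
from .cluster_editing import ClusterEditingConfig, Clustering, cluster_reads
from .core import GAP, AlleleMatrix, Phasing, Read
from .genotools import verify_genotypes
from .scoring import ScoringConfig, build_similarity_graph, estimate_all_windows
from .threading import (
    ClusterProfile,
    Threading,
    ThreadingParams,
    build_cluster_profile,
    derive_haplotypes,
    thread_haplotypes,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one phasing run."""

    ploidy: int
    block_cut_sensitivity: int = 3
    verify_genotypes: bool = False
    p_cov: float = 8.0
    p_switch: float = 32.0
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    cluster_editing: ClusterEditingConfig = field(
        default_factory=ClusterEditingConfig
    )
    tuple_cap: int = 100_000
    max_clusters_per_position: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ploidy < 2:
            raise ValueError("ploidy must be >= 2")
        if self.block_cut_sensitivity not in (1, 2, 3, 4):
            raise ValueError("block-cut sensitivity must be in 1..4")

    def threading_params(self) -> ThreadingParams:
        return ThreadingParams(
            ploidy=self.ploidy,
            p_cov=self.p_cov,
            p_switch=self.p_switch,
            tuple_cap=self.tuple_cap,
            max_clusters_per_position=self.max_clusters_per_position,
        )


@dataclass
class PhaseResult:
    phasing: Phasing
    clustering: Clustering
    threading: Threading
    profile: ClusterProfile
    cuts: blocks_mod.CutSet
    kept_variants: np.ndarray  # mask after genotype verification


def _subset_matrix(matrix: AlleleMatrix, keep: np.ndarray
                   ) -> tuple[AlleleMatrix, np.ndarray]:
    """Restrict a matrix to the kept variant columns (reindexed)."""
    kept_idx = np.flatnonzero(keep)
    new_index = np.full(matrix.n_variants, -1, dtype=np.int64)
    new_index[kept_idx] = np.arange(len(kept_idx))
    variants = []
    for new_i, old_i in enumerate(kept_idx):
        v = matrix.variants[old_i]
        variants.append(
            type(v)(position=v.position, index=new_i, ref_allele=v.ref_allele,
                    alt_allele=v.alt_allele, genotype=v.genotype, chrom=v.chrom)
        )
    reads = []
    for r in matrix.reads:
        sel = keep[r.positions]
        if not sel.any():
            continue
        reads.append(Read(id=r.id, positions=new_index[r.positions[sel]],
                          alleles=r.alleles[sel],
                          true_haplotype=r.true_haplotype))
    return (
        AlleleMatrix(variants=variants, reads=reads, ploidy=matrix.ploidy),
        kept_idx,
    )


def run_phasing(matrix: AlleleMatrix, config: RunConfig) -> PhaseResult:
    """Phase an allele matrix: the two-stage cluster-and-thread algorithm."""
    if matrix.ploidy != config.ploidy:
        raise ValueError(
            f"matrix ploidy {matrix.ploidy} != configured ploidy {config.ploidy}"
        )
    full_n = matrix.n_variants
    keep = np.ones(full_n, dtype=bool)
    if config.verify_genotypes:
        keep = verify_genotypes(matrix)
        work, kept_idx = _subset_matrix(matrix, keep)
    else:
        work, kept_idx = matrix, np.arange(full_n)

    t0 = time.perf_counter()
    est = estimate_all_windows(work, config.scoring)
    graph = build_similarity_graph(work, est)
    logger.info("scoring: %d reads, %d nonzero edges (%.1fs)",
                graph.n_nodes, graph.n_edges, time.perf_counter() - t0)

    t0 = time.perf_counter()
    clustering = cluster_reads(graph, config.cluster_editing)
    logger.info("clustering: %d clusters (%.1fs)",
                clustering.n_clusters, time.perf_counter() - t0)

    t0 = time.perf_counter()
    profile = build_cluster_profile(clustering, work)
    params = config.threading_params()
    threading = thread_haplotypes(profile, work.genotypes, params)
    logger.info("threading: total cost %.1f (%.1fs)",
                threading.total_cost, time.perf_counter() - t0)

    cuts = blocks_mod.compute_cuts(threading, profile,
                                   config.block_cut_sensitivity)
    logger.info("block cuts (level %d): %d", config.block_cut_sensitivity,
                len(cuts))
    hap_sub = derive_haplotypes(threading, profile)

    # expand back to the full variant set (dropped variants stay unphased)
    k = config.ploidy
    hap_full = np.full((k, full_n), GAP, dtype=np.int8)
    hap_full[:, kept_idx] = hap_sub
    phasing_sub = blocks_mod.assign_phase_sets(hap_sub, cuts)
    phase_set = np.full(full_n, GAP, dtype=np.int64)
    haplo_ps = np.full((k, full_n), GAP, dtype=np.int64)
    sub_phased = phasing_sub.phase_set != GAP
    phase_set[kept_idx[sub_phased]] = kept_idx[phasing_sub.phase_set[sub_phased]]
    for t in range(k):
        sub_h = phasing_sub.haplo_phase_set[t] != GAP
        haplo_ps[t, kept_idx[sub_h]] = kept_idx[
            phasing_sub.haplo_phase_set[t, sub_h]
        ]
    hap_full[:, kept_idx[~sub_phased]] = GAP
    phasing = Phasing(
        haplotypes=np.where(phase_set[None, :] != GAP, hap_full, GAP).astype(
            np.int8
        ),
        phase_set=phase_set,
        haplo_phase_set=haplo_ps,
        variants=matrix.variants,
    )
    return PhaseResult(phasing=phasing, clustering=clustering,
                       threading=threading, profile=profile, cuts=cuts,
                       kept_variants=keep)
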