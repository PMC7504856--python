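"""Haplotype threading: assemble k haplotypes through the read clusters.

Cluster editing yields more clusters than haplotypes, each covering only
part of the region, so haplotypes are assembled by choosing a k-tuple of
clusters at every variant (duplicates allowed: locally identical haplotypes
run through one collapsed cluster).  Tuples are filtered by genotype
concordance (consensus alleles must sum to the target genotype, with a +-1
fallback, then no constraint), and a dynamic program minimizes

  * coverage cost: p_cov per tuple slot whose cluster's multiplicity in the
    tuple differs from its expected copy number cn_exp = ceil(k*cov - 1/(2k)),
  * switch cost: p_switch per thread that changes cluster between
    consecutive variants (haplotype contiguity).

DP states are canonical multisets (sorted tuples); the transition cost is
the minimum number of component changes over orderings, k - sum_c
min(mult_prev(c), mult_next(c)).  Thread identities are fixed afterwards by
greedily keeping each thread in its cluster wherever the successor multiset
allows, which realizes that minimum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np

from .cluster_editing import Clustering
from .core import GAP, AlleleMatrix

logger = logging.getLogger(__name__)


@dataclass
class ThreadingParams:
    ploidy: int
    p_cov: float = 8.0
    p_switch: float = 32.0
    #: keep at most this many genotype-eligible multisets per position
    tuple_cap: int = 100_000
    #: consider at most this many clusters per position (top coverage);
    #: None means twice the ploidy
    max_clusters_per_position: int | None = None

    def __post_init__(self) -> None:
        if self.p_cov <= 0 or self.p_switch <= 0:
            raise ValueError("cost constants must be positive")

    @property
    def cluster_cap(self) -> int:
        return (
            self.max_clusters_per_position
            if self.max_clusters_per_position is not None
            else 2 * self.ploidy
        )


@dataclass
class ClusterProfile:
    """Per-cluster consensus and relative coverage along the variants.

    ``cons[c, i]`` is the most frequent allele among reads of cluster ``c``
    at variant ``i`` (ties toward allele 0), or GAP when no read of ``c``
    covers ``i``.  ``cov[c, i]`` is the fraction of reads covering ``i``
    that belong to ``c`` (rows sum to 1 over covered positions).
    ``connected[j]`` records whether any single read covers both variants
    ``j - 1`` and ``j``.
    """

    cons: np.ndarray
    cov: np.ndarray
    connected: np.ndarray

    @property
    def n_clusters(self) -> int:
        return self.cons.shape[0]

    @property
    def n_variants(self) -> int:
        return self.cons.shape[1]

    def covering_clusters(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.cov[:, i] > 0)


@dataclass
class Threading:
    """Chosen cluster multiset per variant plus fixed thread identities.

    ``tuples[j]`` is the canonical (sorted) cluster tuple at variant ``j`` or
    None where the position is unphasable; ``thread_clusters[t, j]`` the
    cluster thread ``t`` runs through (GAP when unphased).
    """

    tuples: list[tuple[int, ...] | None]
    thread_clusters: np.ndarray
    total_cost: float

    @property
    def ploidy(self) -> int:
        return self.thread_clusters.shape[0]

    @property
    def n_variants(self) -> int:
        return self.thread_clusters.shape[1]


def build_cluster_profile(clustering: Clustering,
                          matrix: AlleleMatrix) -> ClusterProfile:
    """Consensus alleles and relative coverage for every cluster."""
    from scipy import sparse

    m, n = matrix.n_reads, matrix.n_variants
    assign = clustering.assignment()
    n_clusters = clustering.n_clusters
    member = sparse.csr_matrix(
        (np.ones(m), (assign, np.arange(m))), shape=(n_clusters, m)
    )
    cover = matrix.coverage_matrix()
    signed = matrix.signed_matrix()
    counts = np.asarray((member @ cover).todense())       # reads of c at i
    netsign = np.asarray((member @ signed).todense())     # (#allele0 - #allele1)

    cons = np.full((n_clusters, n), GAP, dtype=np.int8)
    cons[(counts > 0) & (netsign >= 0)] = 0               # tie -> allele 0
    cons[(counts > 0) & (netsign < 0)] = 1
    ties = int(np.sum((counts > 0) & (netsign == 0) & (counts % 2 == 0)
                      & (counts > 1)))
    if ties:
        logger.debug("%d consensus ties resolved toward allele 0", ties)

    total = counts.sum(axis=0)
    cov = np.divide(counts, np.maximum(total, 1), where=total > 0,
                    out=np.zeros_like(counts, dtype=np.float64))

    covc = cover.tocsc()
    connected = np.zeros(n, dtype=bool)
    if n > 1:
        both = covc[:, 1:].multiply(covc[:, :-1])
        connected[1:] = np.asarray(both.sum(axis=0)).ravel() > 0
    return ClusterProfile(cons=cons, cov=cov, connected=connected)


def expected_copy_number(cov: float, k: int) -> int:
    """Expected number of haplotypes through a cluster: ceil(k*cov - 1/(2k))."""
    return min(max(math.ceil(k * cov - 1.0 / (2 * k)), 0), k)


def coverage_cost(tup: tuple[int, ...], profile: ClusterProfile, i: int,
                  params: ThreadingParams) -> float:
    """p_cov per tuple slot whose cluster multiplicity misses cn_exp."""
    k = params.ploidy
    cost = 0.0
    mult: dict[int, int] = {}
    for c in tup:
        mult[c] = mult.get(c, 0) + 1
    for c in tup:
        if expected_copy_number(float(profile.cov[c, i]), k) != mult[c]:
            cost += params.p_cov
    return cost


def switch_cost(prev: tuple[int, ...], nxt: tuple[int, ...],
                params: ThreadingParams) -> float:
    """p_switch times the minimum number of threads that must change cluster."""
    k = params.ploidy
    mult: dict[int, int] = {}
    for c in prev:
        mult[c] = mult.get(c, 0) + 1
    stay = 0
    for c in nxt:
        if mult.get(c, 0) > 0:
            mult[c] -= 1
            stay += 1
    return params.p_switch * (k - stay)


def eligible_tuples(profile: ClusterProfile, genotypes, i: int,
                    params: ThreadingParams) -> list[tuple[int, ...]]:
    """Genotype-concordant cluster multisets at position i, canonical order.

    Considers the highest-coverage clusters covering i (cluster cap).  If no
    multiset sums to the genotype, a deviation of 1 is allowed; failing
    that, all multisets are eligible.  Returns [] when nothing covers i.
    """
    k = params.ploidy
    covering = profile.covering_clusters(i)
    if covering.size == 0:
        return []
    if covering.size > params.cluster_cap:
        order = np.lexsort((covering, -profile.cov[covering, i]))
        covering = np.sort(covering[order][: params.cluster_cap])
    ones = [int(c) for c in covering if profile.cons[c, i] == 1]
    zeros = [int(c) for c in covering if profile.cons[c, i] == 0]

    def with_alt_counts(alt_counts) -> list[tuple[int, ...]]:
        out = []
        for a in alt_counts:
            if 0 <= a <= k:
                for alt_part in combinations_with_replacement(ones, a):
                    for ref_part in combinations_with_replacement(zeros, k - a):
                        out.append(tuple(sorted(alt_part + ref_part)))
        return out

    g = genotypes[i]
    if g is None:
        tuples = [tuple(sorted(t))
                  for t in combinations_with_replacement(covering.tolist(), k)]
    else:
        tuples = with_alt_counts([int(g)])
        if not tuples:  # allow a genotype deviation of 1
            tuples = with_alt_counts([int(g) - 1, int(g) + 1])
        if not tuples:  # last resort: every multiset of covering clusters
            tuples = [
                tuple(sorted(t))
                for t in combinations_with_replacement(covering.tolist(), k)
            ]
    tuples = sorted(set(tuples))
    if len(tuples) > params.tuple_cap:
        tuples.sort(key=lambda t: (coverage_cost(t, profile, i, params), t))
        tuples = sorted(tuples[: params.tuple_cap])
    return tuples


def _switch_matrix(prev_tuples, next_tuples, k: int) -> np.ndarray:
    """(l_prev, l_next) matrix of minimum thread changes between multisets."""
    clusters = sorted({c for t in prev_tuples for c in t}
                      | {c for t in next_tuples for c in t})
    cid = {c: i for i, c in enumerate(clusters)}
    def counts(tuples):
        out = np.zeros((len(tuples), len(clusters)), dtype=np.int16)
        for r, t in enumerate(tuples):
            for c in t:
                out[r, cid[c]] += 1
        return out
    cp = counts(prev_tuples)
    cn = counts(next_tuples)
    stay = np.minimum(cp[:, None, :], cn[None, :, :]).sum(axis=2)
    return (k - stay).astype(np.float64)


def thread_haplotypes(profile: ClusterProfile, genotypes,
                      params: ThreadingParams) -> Threading:
    """Minimum-cost threading of k haplotypes through the clusters.

    One DP per contiguous run of coverable positions (positions covered by
    no read stay unphased and break the recursion); the optimum is the
    minimum of the last column, recovered by backtracing with ties broken
    toward the lowest row index.
    """
    k = params.ploidy
    n = profile.n_variants
    tuples_per_pos: list[list[tuple[int, ...]]] = []
    for i in range(n):
        tuples_per_pos.append(eligible_tuples(profile, genotypes, i, params))

    chosen: list[tuple[int, ...] | None] = [None] * n
    total_cost = 0.0
    run: list[int] = []
    runs = []
    for i in range(n):
        if tuples_per_pos[i]:
            run.append(i)
        elif run:
            runs.append(run)
            run = []
    if run:
        runs.append(run)

    for run in runs:
        cov_costs = [
            np.array([coverage_cost(t, profile, i, params)
                      for t in tuples_per_pos[i]])
            for i in run
        ]
        score = cov_costs[0]
        backptr: list[np.ndarray] = []
        for step in range(1, len(run)):
            sw = _switch_matrix(tuples_per_pos[run[step - 1]],
                                tuples_per_pos[run[step]], k) * params.p_switch
            via = score[:, None] + sw
            best = np.argmin(via, axis=0)  # lowest predecessor index on ties
            score = via[best, np.arange(via.shape[1])] + cov_costs[step]
            backptr.append(best)
        last = int(np.argmin(score))
        total_cost += float(score[last])
        row = last
        for step in range(len(run) - 1, -1, -1):
            chosen[run[step]] = tuples_per_pos[run[step]][row]
            if step > 0:
                row = int(backptr[step - 1][row])

    thread_clusters = np.full((k, n), GAP, dtype=np.int64)
    prev_assign: list[int] | None = None
    for i in range(n):
        tup = chosen[i]
        if tup is None:
            prev_assign = None
            continue
        if prev_assign is None:
            assign = sorted(tup)
        else:
            remaining: dict[int, int] = {}
            for c in tup:
                remaining[c] = remaining.get(c, 0) + 1
            assign = [-1] * k
            moved = []
            for t in range(k):  # threads stay in their cluster if possible
                c = prev_assign[t]
                if remaining.get(c, 0) > 0:
                    remaining[c] -= 1
                    assign[t] = c
                else:
                    moved.append(t)
            leftovers = sorted(
                c for c, cnt in remaining.items() for _ in range(cnt)
            )
            for t, c in zip(moved, leftovers):
                assign[t] = c
        thread_clusters[:, i] = assign
        prev_assign = assign

    return Threading(tuples=chosen, thread_clusters=thread_clusters,
                     total_cost=total_cost)


def derive_haplotypes(threading: Threading, profile: ClusterProfile) -> np.ndarray:
    """Haplotype allele sequences: H_t[i] = cons(thread_clusters[t, i], i)."""
    k, n = threading.thread_clusters.shape
    hap = np.full((k, n), GAP, dtype=np.int8)
    for t in range(k):
        for i in range(n):
            c = threading.thread_clusters[t, i]
            if c != GAP:
                hap[t, i] = profile.cons[c, i]
    return hap
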