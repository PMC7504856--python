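from __future__ import annotations

import numpy as np
import pytest

from haplothread.cluster_editing import Clustering
from haplothread.core import GAP
from haplothread.threading import (
    ClusterProfile,
    ThreadingParams,
    build_cluster_profile,
    coverage_cost,
    derive_haplotypes,
    eligible_tuples,
    expected_copy_number,
    switch_cost,
    thread_haplotypes,
)

from .conftest import matrix_from_strings
from .oracles import brute_force_threading, oracle_switch_cost


def profile_from(cons, cov) -> ClusterProfile:
    cons = np.asarray(cons, dtype=np.int8)
    cov = np.asarray(cov, dtype=np.float64)
    return ClusterProfile(cons=cons, cov=cov,
                          connected=np.ones(cons.shape[1], dtype=bool))


def random_profile(rng, n_clusters, n_pos, k):
    cov = np.zeros((n_clusters, n_pos))
    cons = np.full((n_clusters, n_pos), GAP, dtype=np.int8)
    genotypes = []
    for j in range(n_pos):
        ncov = int(rng.integers(1, n_clusters + 1))
        which = rng.choice(n_clusters, size=ncov, replace=False)
        weights = rng.random(ncov) + 0.1
        cov[which, j] = weights / weights.sum()
        cons[which, j] = rng.integers(0, 2, size=ncov)
        genotypes.append(int(rng.integers(0, k + 1)) if rng.random() < 0.8
                         else None)
    return profile_from(cons, cov), genotypes


class TestProfile:
    def test_consensus_majority_tie_and_coverage(self):
        # cluster 0 = reads 0,1,2; cluster 1 = read 3
        mat = matrix_from_strings(["001", "000", "011", "110"], ploidy=2)
        clustering = Clustering(clusters=[[0, 1, 2], [3]])
        prof = build_cluster_profile(clustering, mat)
        assert prof.cons[0].tolist() == [0, 0, 1]   # majority vote per column
        assert prof.cov[0].tolist() == [0.75, 0.75, 0.75]
        assert prof.cov[1].tolist() == [0.25, 0.25, 0.25]

    def test_consensus_tie_goes_to_allele_zero(self):
        mat = matrix_from_strings(["01", "00", "11", "10"], ploidy=2)
        clustering = Clustering(clusters=[[0, 1, 2, 3]])
        prof = build_cluster_profile(clustering, mat)
        assert prof.cons[0].tolist() == [0, 0]  # 2-2 ties at both columns

    def test_gap_where_cluster_absent(self):
        mat = matrix_from_strings(["01--", "--10"], ploidy=2)
        clustering = Clustering(clusters=[[0], [1]])
        prof = build_cluster_profile(clustering, mat)
        assert prof.cons[0].tolist() == [0, 1, GAP, GAP]
        assert prof.cons[1].tolist() == [GAP, GAP, 1, 0]

    def test_coverage_sums_to_one_where_covered(self):
        mat = matrix_from_strings(["0101", "0110", "1010"], ploidy=3)
        clustering = Clustering(clusters=[[0, 1], [2]])
        prof = build_cluster_profile(clustering, mat)
        np.testing.assert_allclose(prof.cov.sum(axis=0), 1.0)


class TestCopyNumber:
    @pytest.mark.parametrize(
        "cov,k,expect",
        [(0.25, 4, 1), (0.52, 4, 2), (0.02, 4, 0), (0.0, 4, 0), (1.0, 2, 2)],
    )
    def test_expected_copy_number(self, cov, k, expect):
        assert expected_copy_number(cov, k) == expect


class TestCosts:
    def test_coverage_cost_exact_match_is_free(self):
        # cov chosen so cn_exp = 2, 1, 1 for clusters 0, 1, 2
        prof = profile_from([[0], [1], [0]], [[0.5], [0.25], [0.25]])
        params = ThreadingParams(ploidy=4, p_cov=8.0)
        assert coverage_cost((0, 0, 1, 2), prof, 0, params) == 0.0

    def test_coverage_cost_counts_mismatched_slots(self):
        prof = profile_from([[0], [1]], [[0.5], [0.25]])
        params = ThreadingParams(ploidy=4, p_cov=8.0)
        # cluster 0 appears 3 times (cn_exp 2): three bad slots; cluster 1 ok
        assert coverage_cost((0, 0, 0, 1), prof, 0, params) == 24.0

    def test_switch_cost_examples(self):
        params = ThreadingParams(ploidy=4, p_switch=5.0)
        assert switch_cost((1, 2, 3, 4), (1, 2, 3, 4), params) == 0.0
        assert switch_cost((1, 2, 3, 4), (1, 2, 4, 5), params) == 5.0
        assert switch_cost((1, 1, 2, 2), (3, 3, 4, 4), params) == 20.0

    def test_switch_cost_matches_ordering_brute_force(self, rng):
        for k in (2, 3, 4):
            params = ThreadingParams(ploidy=k, p_switch=1.0)
            for _ in range(50):
                prev = tuple(sorted(rng.integers(0, 4, size=k).tolist()))
                nxt = tuple(sorted(rng.integers(0, 4, size=k).tolist()))
                assert switch_cost(prev, nxt, params) == oracle_switch_cost(
                    prev, nxt, 1.0
                )


class TestEligibleTuples:
    def test_exact_concordance(self):
        prof = profile_from([[0], [1]], [[0.5], [0.5]])
        params = ThreadingParams(ploidy=2)
        assert eligible_tuples(prof, [1], 0, params) == [(0, 1)]
        assert eligible_tuples(prof, [2], 0, params) == [(1, 1)]

    def test_missing_genotype_allows_all_multisets(self):
        prof = profile_from([[0], [1]], [[0.5], [0.5]])
        params = ThreadingParams(ploidy=2)
        assert eligible_tuples(prof, [None], 0, params) == [
            (0, 0), (0, 1), (1, 1)
        ]

    def test_deviation_fallback(self):
        # only allele-0 clusters but genotype 2: fall back to deviation 1
        prof = profile_from([[0], [0]], [[0.5], [0.5]])
        params = ThreadingParams(ploidy=2)
        tuples = eligible_tuples(prof, [2], 0, params)
        assert tuples == [(0, 0), (0, 1), (1, 1)]  # g-1=1 impossible too -> all
        prof2 = profile_from([[0], [1]], [[0.5], [0.5]])
        assert eligible_tuples(prof2, [None], 0, params) == tuples

    def test_uncovered_position_is_unphasable(self):
        prof = profile_from([[0, GAP]], [[1.0, 0.0]])
        params = ThreadingParams(ploidy=2)
        assert eligible_tuples(prof, [1, 1], 1, params) == []


class TestDP:
    def test_two_position_diploid_stays_put(self):
        prof = profile_from([[0, 0], [1, 1]], [[0.5, 0.5], [0.5, 0.5]])
        params = ThreadingParams(ploidy=2)
        thr = thread_haplotypes(prof, [1, 1], params)
        assert thr.tuples == [(0, 1), (0, 1)]
        assert thr.total_cost == 0.0

    def test_single_position_base_case(self):
        prof = profile_from([[0], [1], [1]], [[0.5], [0.4], [0.1]])
        params = ThreadingParams(ploidy=2)
        thr = thread_haplotypes(prof, [1], params)
        # picking cluster 1 (cn_exp 1) beats cluster 2 (cn_exp 0)
        assert thr.tuples[0] == (0, 1)

    def test_dp_equals_brute_force(self, rng):
        for trial in range(40):
            k = int(rng.integers(2, 5))
            n_pos = int(rng.integers(2, 5))
            n_clusters = int(rng.integers(2, 4))
            prof, genotypes = random_profile(rng, n_clusters, n_pos, k)
            params = ThreadingParams(ploidy=k, p_cov=3.0, p_switch=7.0)
            thr = thread_haplotypes(prof, genotypes, params)
            expect, _ = brute_force_threading(
                prof.cons, prof.cov, genotypes, k, 3.0, 7.0
            )
            assert thr.total_cost == pytest.approx(expect)

    def test_gap_positions_stay_unphased(self):
        cons = [[0, GAP, 0], [1, GAP, 1]]
        cov = [[0.5, 0.0, 0.5], [0.5, 0.0, 0.5]]
        prof = profile_from(cons, cov)
        prof.connected[:] = [True, False, False]
        params = ThreadingParams(ploidy=2)
        thr = thread_haplotypes(prof, [1, 1, 1], params)
        assert thr.tuples[1] is None
        assert (thr.thread_clusters[:, 1] == GAP).all()

    def test_more_switch_penalty_never_more_switches(self, rng):
        prof, genotypes = random_profile(rng, 4, 6, 3)
        changes = []
        for p_switch in (1.0, 4.0, 16.0, 64.0):
            params = ThreadingParams(ploidy=3, p_cov=8.0, p_switch=p_switch)
            thr = thread_haplotypes(prof, genotypes, params)
            tc = thr.thread_clusters
            changes.append(int(np.sum(tc[:, 1:] != tc[:, :-1])))
        assert all(a >= b for a, b in zip(changes, changes[1:]))


class TestDeriveHaplotypes:
    def test_haplotype_follows_consensus(self):
        prof = profile_from([[0, 1, 0], [1, 0, 1]],
                            [[0.5, 0.5, 0.5], [0.5, 0.5, 0.5]])
        params = ThreadingParams(ploidy=2)
        thr = thread_haplotypes(prof, [1, 1, 1], params)
        hap = derive_haplotypes(thr, prof)
        assert sorted(map(tuple, hap.tolist())) == [(0, 1, 0), (1, 0, 1)]

    def test_collapsed_cluster_duplicates_haplotype(self):
        prof = profile_from([[1, 1], [0, 0]], [[0.5, 0.5], [0.5, 0.5]])
        params = ThreadingParams(ploidy=4)
        thr = thread_haplotypes(prof, [2, 2], params)
        hap = derive_haplotypes(thr, prof)
        assert hap.sum(axis=0).tolist() == [2, 2]
        # two threads share each cluster -> identical haplotype pairs
        assert len({tuple(h) for h in hap.tolist()}) == 2

    def test_genotype_concordance_at_exact_positions(self, rng):
        for _ in range(10):
            k = int(rng.integers(2, 5))
            prof, genotypes = random_profile(rng, 3, 5, k)
            params = ThreadingParams(ploidy=k)
            thr = thread_haplotypes(prof, genotypes, params)
            hap = derive_haplotypes(thr, prof)
            for j, g in enumerate(genotypes):
                if g is None or thr.tuples[j] is None:
                    continue
                covering = prof.covering_clusters(j)
                sums = {
                    sum(int(prof.cons[c, j]) for c in t)
                    for t in __import__("itertools").combinations_with_replacement(
                        covering.tolist(), k
                    )
                }
                if g in sums:  # an exactly concordant tuple existed
                    assert int(hap[:, j].sum()) == g
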