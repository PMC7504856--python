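"""Independent brute-force oracles used to validate the package's algorithms.

Everything here enumerates exhaustively (partitions, permutations, mapping
sequences, tuple sequences) or evaluates textbook formulas directly; none of
it shares code with the implementation under test.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations_with_replacement, permutations, product

import numpy as np
from scipy.stats import binom

GAP = -1


# ---------------------------------------------------------------------------
# set partitions (restricted growth strings) and exact cluster editing


@lru_cache(maxsize=None)
def all_partitions(n: int) -> np.ndarray:
    """All set partitions of n elements as an array of label vectors."""
    out: list[list[int]] = []

    def grow(labels: list[int], maxlab: int) -> None:
        if len(labels) == n:
            out.append(labels.copy())
            return
        for lab in range(maxlab + 2):
            labels.append(lab)
            grow(labels, max(maxlab, lab))
            labels.pop()

    grow([0], 0)
    return np.array(out, dtype=np.int8)


def exact_cluster_editing(n: int, edges) -> tuple[float, np.ndarray]:
    """Minimum editing cost over all partitions; edges = [(u, v, w), ...].

    Cutting a positive edge costs w; keeping a negative edge inside a
    cluster costs |w|.
    """
    parts = all_partitions(n)
    cost = np.zeros(len(parts))
    for u, v, w in edges:
        same = parts[:, u] == parts[:, v]
        if w > 0:
            cost += np.where(same, 0.0, w)
        elif w < 0:
            cost += np.where(same, -w, 0.0)
    best = int(np.argmin(cost))
    return float(cost[best]), parts[best]


# ---------------------------------------------------------------------------
# similarity score via the binomial pmf ratio


def pmf_ratio_score(dis: int, olp: int, d_same: float, d_diff: float) -> float:
    """log of the ratio of binomial pmfs, evaluated with scipy."""
    return float(
        binom.logpmf(dis, olp, d_same) - binom.logpmf(dis, olp, d_diff)
    )


# ---------------------------------------------------------------------------
# Hamming error / switch error by exhaustive enumeration


def brute_force_hamming(truth: np.ndarray, pred: np.ndarray) -> float:
    """min over all k! permutations of the mean Hamming distance."""
    k = truth.shape[0]
    best = np.inf
    for sigma in permutations(range(k)):
        total = 0
        for i in range(k):
            p = pred[sigma[i]]
            total += np.sum((truth[i] != p) & (p != GAP))
        best = min(best, total / k)
    return float(best)


def consistent_mappings(truth_col, pred_col) -> list[tuple[int, ...]]:
    """All bijections pi with truth[i] == pred[pi[i]], by filtering k!."""
    k = len(truth_col)
    out = []
    for pi in permutations(range(k)):
        if all(truth_col[i] == pred_col[pi[i]] for i in range(k)):
            out.append(pi)
    return out


def brute_force_switches(truth: np.ndarray, pred: np.ndarray) -> int:
    """Minimum summed mapping changes over all mapping sequences.

    Enumerates the full product Pi_1 x ... x Pi_m by expanding a cost array
    combination by combination; the minimum is taken only at the very end.
    """
    m = truth.shape[1]
    mapping_arrays = [
        np.array(consistent_mappings(truth[:, j], pred[:, j])) for j in range(m)
    ]
    assert all(len(a) for a in mapping_arrays), "no consistent mapping"
    costs = np.zeros(len(mapping_arrays[0]))            # one per combination
    last = np.arange(len(mapping_arrays[0]))            # its current mapping
    for j in range(1, m):
        prev_arr, next_arr = mapping_arrays[j - 1], mapping_arrays[j]
        ds = (prev_arr[:, None, :] != next_arr[None, :, :]).sum(axis=2)
        costs = (costs[:, None] + ds[last, :]).reshape(-1)
        last = np.tile(np.arange(len(next_arr)), costs.size // len(next_arr))
    return int(costs.min())


def brute_force_ser(truth: np.ndarray, pred: np.ndarray) -> float:
    k, m = truth.shape
    if m < 2:
        return 0.0
    return brute_force_switches(truth, pred) / (k * (m - 1))


# ---------------------------------------------------------------------------
# threading by exhaustive search over tuple sequences


def oracle_switch_cost(prev: tuple[int, ...], nxt: tuple[int, ...],
                       p_switch: float) -> float:
    """Minimum component changes over all k! orderings of the successor."""
    k = len(prev)
    best = min(
        sum(1 for a, b in zip(prev, perm) if a != b)
        for perm in set(permutations(nxt))
    )
    return p_switch * best


def oracle_eligible(cons_col, cov_col, genotype, k) -> list[tuple[int, ...]]:
    """Genotype-concordant multisets by filtering all multisets."""
    covering = [c for c in range(len(cov_col)) if cov_col[c] > 0]
    if not covering:
        return []
    universe = [tuple(sorted(t))
                for t in combinations_with_replacement(covering, k)]
    if genotype is None:
        return sorted(set(universe))
    def gsum(t):
        return sum(cons_col[c] for c in t)
    for accept in (
        lambda t: gsum(t) == genotype,
        lambda t: abs(gsum(t) - genotype) == 1,
        lambda t: True,
    ):
        sel = sorted({t for t in universe if accept(t)})
        if sel:
            return sel
    return []


def oracle_coverage_cost(tup, cov_col, k, p_cov) -> float:
    import math
    from collections import Counter

    mult = Counter(tup)
    cost = 0.0
    for c in tup:
        cn_exp = min(max(math.ceil(k * cov_col[c] - 1 / (2 * k)), 0), k)
        if cn_exp != mult[c]:
            cost += p_cov
    return cost


def brute_force_threading(cons, cov, genotypes, k, p_cov, p_switch
                          ) -> tuple[float, list[tuple[int, ...]]]:
    """Exhaustive minimum over all eligible tuple sequences.

    Per-position coverage costs and per-junction switch costs (each found by
    brute force over orderings) are tabulated first; then every sequence in
    the full product is evaluated.
    """
    n = cons.shape[1]
    per_pos = [oracle_eligible(cons[:, j], cov[:, j], genotypes[j], k)
               for j in range(n)]
    assert all(per_pos)
    cov_cost = [
        {t: oracle_coverage_cost(t, cov[:, j], k, p_cov) for t in per_pos[j]}
        for j in range(n)
    ]
    sw_cost = [
        {
            (a, b): oracle_switch_cost(a, b, p_switch)
            for a in per_pos[j - 1] for b in per_pos[j]
        }
        for j in range(1, n)
    ]
    best_cost, best_seq = np.inf, None
    for seq in product(*per_pos):
        cost = sum(cov_cost[j][seq[j]] for j in range(n))
        cost += sum(sw_cost[j - 1][(seq[j - 1], seq[j])] for j in range(1, n))
        if cost < best_cost:
            best_cost, best_seq = cost, seq
    return float(best_cost), list(best_seq)
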