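"""Polyploid phasing accuracy metrics.

Two error notions, both invariant to the arbitrary order of predicted
haplotypes:

* Hamming errors HE: minimum over all permutations sigma of the mean
  Hamming distance (1/k) sum_i d_H(h_i, h*_sigma(i)) between truth and
  prediction; the Hamming rate HR divides the summed HE by the number of
  phased variants.
* Switch (vector) error rate SER: at every position j the set Pi_j of
  one-to-one truth-to-prediction mappings consistent with the alleles is
  considered; SER is the minimum over mapping sequences of the number of
  per-junction mapping changes d_S, normalized by k(m-1).  Positions whose
  predicted genotype differs from the truth admit no consistent mapping and
  are excluded, counted into the missing-variant fraction MV instead.

Block-wise aggregation sums the error counts over blocks and divides by the
total number of (phased) variants for HR, and by k times the total number
of compared variants excluding the first of every block for SER.  N50 is
the smallest block length needed to cover half the region using only blocks
at least that long.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import GAP, Phasing


@dataclass
class EvaluationResult:
    ser: float
    hamming_rate: float
    missing_variants: float
    n50: float
    n50_unit: str = "bp"
    n_blocks: int = 0
    n_variants: int = 0
    n_phased: int = 0
    n_compared: int = 0
    switch_errors: int = 0
    hamming_errors: float = 0.0
    per_block: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "SER": self.ser,
            "HR": self.hamming_rate,
            "MV": self.missing_variants,
            "N50": self.n50,
            "N50_unit": self.n50_unit,
            "n_blocks": self.n_blocks,
            "n_variants": self.n_variants,
            "n_phased": self.n_phased,
            "n_compared": self.n_compared,
            "switch_errors": self.switch_errors,
            "hamming_errors": self.hamming_errors,
        }


# ---------------------------------------------------------------------------
# Hamming error


def hamming_error(truth: np.ndarray, pred: np.ndarray) -> float:
    """Permutation-minimized mean Hamming distance between haplotype sets.

    Positions where a predicted haplotype is unphased (GAP) do not count
    against it.  The minimum over all k! pairings is found as a linear
    assignment (exact for this sum objective).
    """
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise ValueError("truth/prediction shape mismatch")
    k = truth.shape[0]
    valid = pred != GAP  # (k, n), per predicted haplotype
    cost = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            cost[i, j] = np.sum((truth[i] != pred[j]) & valid[j])
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].sum()) / k


# ---------------------------------------------------------------------------
# switch / vector error


def position_mappings(truth_col: np.ndarray, pred_col: np.ndarray
                      ) -> list[tuple[int, ...]]:
    """All one-to-one mappings pi with truth[i] == pred[pi[i]] at a position.

    Empty when the genotypes (allele counts) differ.
    """
    k = len(truth_col)
    t0 = [i for i in range(k) if truth_col[i] == 0]
    t1 = [i for i in range(k) if truth_col[i] == 1]
    p0 = [j for j in range(k) if pred_col[j] == 0]
    p1 = [j for j in range(k) if pred_col[j] == 1]
    if len(t0) != len(p0) or GAP in truth_col or GAP in pred_col:
        return []
    out = []
    for perm0 in permutations(p0):
        for perm1 in permutations(p1):
            pi = [0] * k
            for i, j in zip(t0, perm0):
                pi[i] = j
            for i, j in zip(t1, perm1):
                pi[i] = j
            out.append(tuple(pi))
    return sorted(out)


def _min_switches(truth: np.ndarray, pred: np.ndarray,
                  positions: np.ndarray) -> int:
    """Minimum summed d_S over consistent mapping sequences (DP over Pi_j)."""
    if len(positions) < 2:
        return 0
    maps_prev = position_mappings(truth[:, positions[0]], pred[:, positions[0]])
    score = np.zeros(len(maps_prev))
    prev_arr = np.array(maps_prev)
    for j in positions[1:]:
        maps_next = position_mappings(truth[:, j], pred[:, j])
        next_arr = np.array(maps_next)
        # d_S between every mapping pair: number of differing images
        ds = (prev_arr[:, None, :] != next_arr[None, :, :]).sum(axis=2)
        score = np.min(score[:, None] + ds, axis=0)
        prev_arr = next_arr
    return int(np.min(score))


def compared_positions(truth: np.ndarray, pred: np.ndarray) -> np.ndarray:
    """Positions that are phased and whose predicted genotype is correct."""
    phased = np.all(pred != GAP, axis=0)
    correct = truth.sum(axis=0) == np.where(pred == GAP, 0, pred).sum(axis=0)
    return np.flatnonzero(phased & correct)


def switch_error_rate(truth: np.ndarray, pred: np.ndarray) -> float:
    """Vector error rate over one block of predictions.

    Only phased, genotype-correct positions are compared; with fewer than
    two such positions the rate is reported as 0.
    """
    pos = compared_positions(np.asarray(truth), np.asarray(pred))
    if len(pos) < 2:
        return 0.0
    k = truth.shape[0]
    return _min_switches(truth, pred, pos) / (k * (len(pos) - 1))


# ---------------------------------------------------------------------------
# block-wise aggregation and N50


def n50(block_spans, region_length: float) -> float:
    """Smallest block length covering half the region with blocks >= it."""
    spans = sorted((float(s) for s in block_spans), reverse=True)
    cum = 0.0
    for s in spans:
        cum += s
        if cum >= region_length / 2.0:
            return s
    return 0.0


def blockwise_metrics(truth: np.ndarray, phasing: Phasing,
                      n50_unit: str = "bp") -> EvaluationResult:
    """Aggregate HE/SER/MV/N50 over the phase blocks of a prediction.

    Haplotype permutations are minimized per block.  ``n50_unit`` is "bp"
    (genomic spans from the variant coordinates) or "variants".
    """
    truth = np.asarray(truth)
    k, n = truth.shape
    pred = phasing.haplotypes
    blocks = phasing.blocks()
    phased = np.flatnonzero(phasing.phase_set != GAP)
    n_phased = len(phased)

    total_he = 0.0
    total_sw = 0
    total_cmp = 0
    junctions = 0
    spans = []
    per_block = []
    if phasing.variants:
        positions = np.array([v.position for v in phasing.variants])
    else:
        positions = np.arange(n) + 1

    for block in blocks:
        bt, bp = truth[:, block], pred[:, block]
        he = hamming_error(bt, bp)
        cmp_pos = compared_positions(bt, bp)
        sw = _min_switches(bt, bp, cmp_pos)
        total_he += he
        total_sw += sw
        total_cmp += len(cmp_pos)
        junctions += max(0, len(cmp_pos) - 1)
        if n50_unit == "bp":
            spans.append(positions[block[-1]] - positions[block[0]] + 1)
        else:
            spans.append(len(block))
        per_block.append({
            "start": int(block[0]),
            "end": int(block[-1]) + 1,
            "n_variants": len(block),
            "n_compared": len(cmp_pos),
            "hamming_errors": he,
            "switch_errors": sw,
        })

    genotype_ok = truth.sum(axis=0) == np.where(pred == GAP, 0, pred).sum(axis=0)
    mv = (n - np.sum((phasing.phase_set != GAP) & genotype_ok)) / n if n else 0.0
    hr = total_he / n_phased if n_phased else 0.0
    ser = total_sw / (k * junctions) if junctions else 0.0
    if n50_unit == "bp":
        region = float(positions[-1] - positions[0] + 1) if n else 0.0
    else:
        region = float(n)
    return EvaluationResult(
        ser=ser,
        hamming_rate=hr,
        missing_variants=float(mv),
        n50=n50(spans, region),
        n50_unit=n50_unit,
        n_blocks=len(blocks),
        n_variants=n,
        n_phased=n_phased,
        n_compared=total_cmp,
        switch_errors=int(total_sw),
        hamming_errors=float(total_he),
        per_block=per_block,
    )


# ---------------------------------------------------------------------------
# collapsing regions


def find_collapsing_regions(truth: np.ndarray,
                            min_len: int = 50) -> list[tuple[int, int]]:
    """Maximal variant intervals where >= 2 haplotypes are identical.

    A region requires some haplotype pair to agree on at least ``min_len``
    consecutive variants; overlapping intervals from different pairs are
    merged.
    """
    truth = np.asarray(truth)
    k, n = truth.shape
    intervals = []
    for a in range(k):
        for b in range(a + 1, k):
            eq = truth[a] == truth[b]
            start = None
            for i in range(n + 1):
                if i < n and eq[i]:
                    if start is None:
                        start = i
                elif start is not None:
                    if i - start >= min_len:
                        intervals.append((start, i))
                    start = None
    intervals.sort()
    merged: list[list[int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]
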