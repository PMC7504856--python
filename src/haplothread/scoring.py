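"""Read-pair similarity scoring.

Overlapping read pairs are scored by a binomial log-likelihood ratio: the
number of disagreements ``dis`` in an overlap of ``olp`` shared variants is
binomially distributed with rate ``d_same`` if the reads come from the same
haplotype and ``d_diff`` otherwise.  The score

    log f(dis, olp, d_same) - log f(dis, olp, d_diff)

is positive for same-haplotype evidence and negative otherwise.  Binomial
coefficients cancel, so the score reduces to the closed form

    dis * ln(d_same / d_diff) + (olp - dis) * ln((1 - d_same) / (1 - d_diff)).

Because haplotype dissimilarity varies along the genome, the rates are
estimated per window of average read length: ``d_same`` as the mean of the
lowest 1/k fraction of pair Hamming rates (a 1/k fraction of pairs is
expected to be same-haplotype), ``d_all`` as the mean over all pairs, and
``d_diff`` from d_all ~ (1/k) d_same + (k-1)/k d_diff.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .core import AlleleMatrix, Read

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoringConfig:
    epsilon: float = 1e-3           # clamp rates into [eps, 0.5 - eps]
    default_d_same: float = 0.07    # used when no pair exists anywhere
    default_d_diff: float = 0.35
    min_overlap: int = 2            # pairs below this overlap score exactly 0


@dataclass
class WindowEstimates:
    """Per-window dissimilarity-rate estimates.

    ``windows`` are half-open [start, end) variant-index intervals that
    partition [0, n); the rate arrays are aligned with them.
    """

    windows: list[tuple[int, int]]
    d_same: np.ndarray
    d_diff: np.ndarray
    d_all: np.ndarray
    config: ScoringConfig = field(default_factory=ScoringConfig)

    def window_of(self, variant_index: int) -> int:
        starts = [w[0] for w in self.windows]
        i = int(np.searchsorted(starts, variant_index, side="right")) - 1
        if i < 0 or variant_index >= self.windows[i][1]:
            raise IndexError(f"variant {variant_index} outside all windows")
        return i

    @classmethod
    def uniform(cls, n: int, d_same: float, d_diff: float,
                config: ScoringConfig | None = None) -> "WindowEstimates":
        """Single-window estimates with fixed rates (mainly for tests)."""
        cfg = config or ScoringConfig()
        k = 2.0
        return cls(
            windows=[(0, n)],
            d_same=np.array([d_same]),
            d_diff=np.array([d_diff]),
            d_all=np.array([(d_same + d_diff) / k]),
            config=cfg,
        )


@dataclass
class SimilarityGraph:
    """Reads as nodes, log-ratio scores as edge weights.

    Only nonzero edges are stored: ``us``/``vs`` (with us < vs) and
    ``weights`` are parallel arrays.  Non-overlapping pairs and pairs with
    overlap below the minimum have an implicit weight of exactly 0.
    """

    n_nodes: int
    us: np.ndarray
    vs: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self._adj: list[dict[int, float]] | None = None

    @property
    def n_edges(self) -> int:
        return len(self.weights)

    def adjacency(self) -> list[dict[int, float]]:
        if self._adj is None:
            adj: list[dict[int, float]] = [dict() for _ in range(self.n_nodes)]
            for u, v, w in zip(self.us.tolist(), self.vs.tolist(),
                               self.weights.tolist()):
                adj[u][v] = w
                adj[v][u] = w
            self._adj = adj
        return self._adj

    def weight(self, u: int, v: int) -> float:
        return self.adjacency()[u].get(v, 0.0)


# ---------------------------------------------------------------------------


def partition_windows(matrix: AlleleMatrix) -> list[tuple[int, int]]:
    """Partition variant columns into windows of average read length.

    Window size is the rounded mean number of variants covered per read
    (minimum 1); the last window may be shorter.
    """
    n = matrix.n_variants
    if n < 1:
        raise ValueError("empty matrix")
    size = max(1, round(matrix.mean_read_span()))
    return [(s, min(s + size, n)) for s in range(0, n, size)]


def _pair_arrays(matrix: AlleleMatrix, lo: int = 0, hi: int | None = None):
    """(keys, olp, dis) over read pairs sharing >= 1 variant in [lo, hi).

    Keys are u * m + v with u < v, sorted ascending.
    """
    m = matrix.n_reads
    cov = matrix.coverage_matrix()[:, lo:hi]
    sig = matrix.signed_matrix()[:, lo:hi]
    olp = sparse.triu(cov @ cov.T, k=1).tocoo()
    agree = sparse.triu(sig @ sig.T, k=1).tocoo()
    keys = olp.row.astype(np.int64) * m + olp.col
    order = np.argsort(keys)
    keys, olp_v = keys[order], olp.data[order].astype(np.int64)
    akeys = agree.row.astype(np.int64) * m + agree.col
    aorder = np.argsort(akeys)
    akeys, agree_v = akeys[aorder], agree.data[aorder].astype(np.int64)
    # agreement pattern is a subset of the overlap pattern (values may cancel
    # to zero and be pruned); align on the overlap pattern
    agree_full = np.zeros(len(keys), dtype=np.int64)
    pos = np.searchsorted(keys, akeys)
    agree_full[pos] = agree_v
    dis_v = (olp_v - agree_full) // 2
    return keys, olp_v, dis_v


def _clamp_rates(d_same: float, d_diff: float, d_all: float,
                 cfg: ScoringConfig) -> tuple[float, float, float]:
    eps = cfg.epsilon
    lo, hi = eps, 0.5 - eps
    d_same = min(max(d_same, lo), hi)
    d_diff = min(max(d_diff, lo), hi)
    d_all = min(max(d_all, lo), hi)
    if d_same >= d_diff:  # degenerate window: force the rates apart
        logger.warning("degenerate rate estimates (d_same >= d_diff); forcing apart")
        d_diff = min(d_same + eps, hi)
        if d_same >= d_diff:
            d_same = d_diff - eps
    return d_same, d_diff, d_all


def _rates_from_hamming(rates: np.ndarray, k: int,
                        cfg: ScoringConfig) -> tuple[float, float, float]:
    rates = np.sort(rates)
    n_low = math.ceil(len(rates) / k)
    d_same = float(rates[:n_low].mean())
    d_all = float(rates.mean())
    d_diff = (k * d_all - d_same) / (k - 1)
    return _clamp_rates(d_same, d_diff, d_all, cfg)


def estimate_rates(
    matrix: AlleleMatrix,
    window: tuple[int, int],
    config: ScoringConfig | None = None,
    _global: tuple[float, float, float] | None = None,
) -> tuple[float, float, float]:
    """Estimate (d_same, d_diff, d_all) from pairs overlapping a window.

    Pairs must have a total overlap of at least ``min_overlap``; the Hamming
    rate entering the estimate is the within-window portion of the pair's
    overlap.  Falls back to global estimates when the window has no pair, and
    to configured defaults (with a warning) when no pair exists at all.
    """
    cfg = config or ScoringConfig()
    k = matrix.ploidy
    keys_all, olp_all, _ = _pair_arrays(matrix)
    eligible = keys_all[olp_all >= cfg.min_overlap]
    keys_w, olp_w, dis_w = _pair_arrays(matrix, window[0], window[1])
    sel = np.isin(keys_w, eligible, assume_unique=True)
    if sel.any():
        return _rates_from_hamming(dis_w[sel] / olp_w[sel], k, cfg)
    if _global is None:
        _global = _global_rates(matrix, cfg)
    return _global


def _global_rates(matrix: AlleleMatrix,
                  cfg: ScoringConfig) -> tuple[float, float, float]:
    keys, olp, dis = _pair_arrays(matrix)
    mask = olp >= cfg.min_overlap
    if not mask.any():
        logger.warning("no overlapping read pairs; using default rates")
        d_all = (cfg.default_d_same +
                 (matrix.ploidy - 1) * cfg.default_d_diff) / matrix.ploidy
        return _clamp_rates(cfg.default_d_same, cfg.default_d_diff, d_all, cfg)
    return _rates_from_hamming(dis[mask] / olp[mask], matrix.ploidy, cfg)


def estimate_all_windows(matrix: AlleleMatrix,
                         config: ScoringConfig | None = None) -> WindowEstimates:
    """Window the variants and estimate rates per window."""
    cfg = config or ScoringConfig()
    windows = partition_windows(matrix)
    glob = _global_rates(matrix, cfg)
    ds, dd, da = [], [], []
    keys_all, olp_all, _ = _pair_arrays(matrix)
    eligible = keys_all[olp_all >= cfg.min_overlap]
    for lo, hi in windows:
        keys_w, olp_w, dis_w = _pair_arrays(matrix, lo, hi)
        sel = np.isin(keys_w, eligible, assume_unique=True)
        if sel.any():
            s, d, a = _rates_from_hamming(dis_w[sel] / olp_w[sel],
                                          matrix.ploidy, cfg)
        else:
            s, d, a = glob
        ds.append(s)
        dd.append(d)
        da.append(a)
    return WindowEstimates(windows=windows, d_same=np.array(ds),
                           d_diff=np.array(dd), d_all=np.array(da), config=cfg)


def log_ratio_score(dis, olp, d_same, d_diff):
    """Closed-form binomial log-likelihood-ratio score (vectorized)."""
    dis = np.asarray(dis, dtype=np.float64)
    olp = np.asarray(olp, dtype=np.float64)
    return dis * np.log(np.asarray(d_same) / np.asarray(d_diff)) + (
        olp - dis
    ) * np.log((1.0 - np.asarray(d_same)) / (1.0 - np.asarray(d_diff)))


def score_pair(r: Read, s: Read, est: WindowEstimates) -> float:
    """Similarity score of a read pair under the window estimates.

    Pairs overlapping on fewer than ``min_overlap`` variants get a neutral
    score of exactly 0.  When the overlap spans several windows, the
    effective rates are the overlap-weighted means of the window rates.
    """
    cfg = est.config
    shared = np.intersect1d(r.positions, s.positions, assume_unique=True)
    olp = shared.size
    if olp < cfg.min_overlap:
        return 0.0
    common, ri, si = np.intersect1d(
        r.positions, s.positions, assume_unique=True, return_indices=True
    )
    dis = int(np.sum(r.alleles[ri] != s.alleles[si]))
    starts = np.array([w[0] for w in est.windows])
    widx = np.searchsorted(starts, shared, side="right") - 1
    d_same = float(est.d_same[widx].mean())
    d_diff = float(est.d_diff[widx].mean())
    return float(log_ratio_score(dis, olp, d_same, d_diff))


def build_similarity_graph(matrix: AlleleMatrix,
                           est: WindowEstimates | None = None,
                           config: ScoringConfig | None = None) -> SimilarityGraph:
    """Score all overlapping read pairs and assemble the similarity graph.

    One node per read; a (possibly negative) weighted edge for every pair
    with overlap >= min_overlap.  Zero-weight pairs are left implicit.
    """
    cfg = config or ScoringConfig()
    if est is None:
        est = estimate_all_windows(matrix, cfg)
    else:
        cfg = est.config
    m = matrix.n_reads
    keys, olp, dis = _pair_arrays(matrix)
    mask = olp >= cfg.min_overlap
    keys, olp, dis = keys[mask], olp[mask], dis[mask]

    eff_ds = np.zeros(len(keys))
    eff_dd = np.zeros(len(keys))
    for widx, (lo, hi) in enumerate(est.windows):
        if len(keys) == 0:
            break
        keys_w, olp_w, _ = _pair_arrays(matrix, lo, hi)
        pos = np.searchsorted(keys, keys_w)
        pos_c = np.minimum(pos, len(keys) - 1)
        valid = keys[pos_c] == keys_w
        np.add.at(eff_ds, pos_c[valid], olp_w[valid] * est.d_same[widx])
        np.add.at(eff_dd, pos_c[valid], olp_w[valid] * est.d_diff[widx])
    eff_ds /= np.maximum(olp, 1)
    eff_dd /= np.maximum(olp, 1)

    scores = log_ratio_score(dis, olp, eff_ds, eff_dd)
    nz = scores != 0.0
    keys, scores = keys[nz], scores[nz]
    return SimilarityGraph(
        n_nodes=m,
        us=(keys // m).astype(np.int64),
        vs=(keys % m).astype(np.int64),
        weights=scores,
    )
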