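"""Greedy cluster editing on the read-similarity graph.

Cluster editing transforms a weighted graph into disjoint cliques at minimum
cost: deleting a present (positive) edge costs its weight, inserting a
missing (negative) edge costs its absolute weight.  Exact solving is
NP-hard, so reads are clustered with a greedy heuristic that repeatedly
picks the most consequential undecided edge and fixes it as *permanent*
(merging its endpoints) or *forbidden* (weight set to -inf).

The choice is driven by induced costs:

    icf(u,v) = max(0, w(u,v)) + sum over common neighbours z with
               w(u,z) > 0 and w(v,z) > 0 of min(w(u,z), w(v,z))
    icp(u,v) = max(0, -w(u,v)) + sum over z with w(u,z) * w(v,z) < 0 of
               min(|w(u,z)|, |w(v,z)|)

icf is the cost of forbidding the edge, icp the cost of making it permanent.
The edge maximizing max(icp, icf) is decided first (ties: larger |w|, then
lexicographic node ids); it becomes permanent when icf >= icp.  Zero-edges
(non-overlapping pairs) are not materialized and never decided explicitly --
a zero-edge between reads that end up in one merged node is implicitly
inserted by the contraction.  The number of clusters is data-driven, never
forced to the ploidy.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .scoring import SimilarityGraph

logger = logging.getLogger(__name__)

NEG_INF = float("-inf")


class EdgeCosts(NamedTuple):
    icp: float
    icf: float


@dataclass
class ClusterEditingConfig:
    #: "induced_cost": argmax of max(icp, icf); "weight": argmax of |w|
    tie_break: str = "induced_cost"
    #: abort threshold for a single connected component
    max_component_size: int = 100_000


@dataclass
class Clustering:
    """Disjoint read clusters; ids are stable (sorted by smallest member)."""

    clusters: list[list[int]]
    n_reads: int = 0

    def __post_init__(self) -> None:
        if self.n_reads == 0 and self.clusters:
            self.n_reads = sum(len(c) for c in self.clusters)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def assignment(self) -> np.ndarray:
        out = np.full(self.n_reads, -1, dtype=np.int64)
        for cid, members in enumerate(self.clusters):
            out[np.asarray(members, dtype=np.int64)] = cid
        return out


def induced_costs(graph: SimilarityGraph, edge: tuple[int, int]) -> EdgeCosts:
    """Induced costs of making an edge permanent (icp) or forbidden (icf)."""
    adj = graph.adjacency()
    u, v = edge
    w = adj[u].get(v, 0.0)
    if w in (NEG_INF, float("inf")):
        raise ValueError(f"edge {edge} is already decided")
    icf = max(0.0, w)
    icp = max(0.0, -w)
    small, other = (adj[u], adj[v]) if len(adj[u]) <= len(adj[v]) else (adj[v], adj[u])
    for z, wz in small.items():
        if z == u or z == v:
            continue
        wo = other.get(z)
        if wo is None:
            continue
        if wz > 0 and wo > 0:
            icf += min(wz, wo)
        elif (wz > 0) != (wo > 0):
            icp += min(abs(wz), abs(wo))
    return EdgeCosts(icp=icp, icf=icf)


def _icf_term(w1: float, w2: float) -> float:
    if w1 is None or w2 is None:
        return 0.0
    return min(w1, w2) if (w1 > 0 and w2 > 0) else 0.0


def _icp_term(w1: float, w2: float) -> float:
    if w1 is None or w2 is None:
        return 0.0
    if (w1 > 0) == (w2 > 0):
        return 0.0
    a1 = -w1 if w1 < 0 else w1
    a2 = -w2 if w2 < 0 else w2
    return a1 if a1 < a2 else a2


class _GreedySolver:
    """Incremental permanent/forbidden greedy on one connected component.

    Maintains icf/icp for all undecided edges under weight changes (merges
    and forbids) and selects decisions through a lazy max-heap: every icost
    increase pushes a fresh entry; stale entries are detected on pop by
    comparing against the current priority and replaced, so the accepted
    entry is always a true argmax.
    """

    def __init__(self, n: int, edges, by_weight: bool = False):
        self.n = n
        self.by_weight = by_weight
        self.adj: list[dict[int, float]] = [dict() for _ in range(n)]
        for u, v, w in edges:
            self.adj[u][v] = w
            self.adj[v][u] = w
        self.members: dict[int, list[int]] = {u: [u] for u in range(n)}
        self.icf: dict[int, float] = {}
        self.icp: dict[int, float] = {}
        self.cur: dict[int, float] = {}
        self.heap: list = []
        for u in range(n):
            for v, w in self.adj[u].items():
                if u < v:
                    key = u * n + v
                    c = self._scratch(u, v)
                    self.icf[key], self.icp[key] = c
                    self._set_prio(key, u, v)

    # -- induced-cost bookkeeping ------------------------------------------

    def _scratch(self, u: int, v: int) -> tuple[float, float]:
        w = self.adj[u][v]
        icf = w if w > 0 else 0.0
        icp = -w if w < 0 else 0.0
        small, other = (
            (self.adj[u], self.adj[v])
            if len(self.adj[u]) <= len(self.adj[v])
            else (self.adj[v], self.adj[u])
        )
        for z, wz in small.items():
            if z == u or z == v:
                continue
            wo = other.get(z)
            if wo is None:
                continue
            if wz > 0 and wo > 0:
                icf += wz if wz < wo else wo
            elif (wz > 0) != (wo > 0):
                a1 = -wz if wz < 0 else wz
                a2 = -wo if wo < 0 else wo
                icp += a1 if a1 < a2 else a2
        return icf, icp

    def _priority(self, key: int) -> float:
        if self.by_weight:
            u, v = divmod(key, self.n)
            w = self.adj[u][v]
            return -w if w < 0 else w
        a, b = self.icf[key], self.icp[key]
        return a if a > b else b

    def _set_prio(self, key: int, u: int, v: int) -> None:
        p = self._priority(key)
        self.cur[key] = p
        w = self.adj[u][v]
        heapq.heappush(self.heap, (-p, -(w if w > 0 else -w), u, v))

    def _set_weight(self, a: int, b: int, new: float | None,
                    touched: set[int]) -> None:
        """Change w(a,b) (None removes the edge), updating all icosts."""
        adj_a, adj_b = self.adj[a], self.adj[b]
        old = adj_a.get(b)
        small, sa = (adj_a, a) if len(adj_a) <= len(adj_b) else (adj_b, b)
        other = adj_b if sa == a else adj_a
        icf, icp = self.icf, self.icp
        nn = self.n
        for z, wz in small.items():
            if z == a or z == b:
                continue
            wo = other.get(z)
            if wo is None:
                continue
            # (wz, wo) are the weights from z to (small-owner, other-owner)
            w_az = wz if sa == a else wo  # weight (a, z)
            w_bz = wo if sa == a else wz  # weight (b, z)
            kaz = a * nn + z if a < z else z * nn + a
            if kaz in icf:
                icf[kaz] += _icf_term(new, w_bz) - _icf_term(old, w_bz)
                icp[kaz] += _icp_term(new, w_bz) - _icp_term(old, w_bz)
                touched.add(kaz)
            kbz = b * nn + z if b < z else z * nn + b
            if kbz in icf:
                icf[kbz] += _icf_term(new, w_az) - _icf_term(old, w_az)
                icp[kbz] += _icp_term(new, w_az) - _icp_term(old, w_az)
                touched.add(kbz)
        key = a * nn + b if a < b else b * nn + a
        if new is None:
            adj_a.pop(b, None)
            adj_b.pop(a, None)
            icf.pop(key, None)
            icp.pop(key, None)
            self.cur.pop(key, None)
            touched.discard(key)
        else:
            adj_a[b] = new
            adj_b[a] = new
            if new == NEG_INF:  # decided: no induced costs tracked
                icf.pop(key, None)
                icp.pop(key, None)
                self.cur.pop(key, None)
                touched.discard(key)
            else:
                icf[key], icp[key] = self._scratch(a, b)
                touched.add(key)

    def _flush(self, touched: set[int]) -> None:
        for key in touched:
            if key not in self.icf:
                continue
            p = self._priority(key)
            if p > self.cur.get(key, NEG_INF):
                u, v = divmod(key, self.n)
                self._set_prio(key, u, v)
            else:
                self.cur[key] = p

    # -- decisions ----------------------------------------------------------

    def _forbid(self, u: int, v: int) -> None:
        touched: set[int] = set()
        self._set_weight(u, v, NEG_INF, touched)
        self._flush(touched)

    def _merge(self, u: int, v: int) -> None:
        keep, gone = (
            (u, v) if (len(self.adj[u]), -u) >= (len(self.adj[v]), -v) else (v, u)
        )
        touched: set[int] = set()
        self._set_weight(keep, gone, None, touched)
        for x in sorted(self.adj[gone]):
            wx = self.adj[gone][x]
            cur_w = self.adj[keep].get(x)
            self._set_weight(gone, x, None, touched)
            new_w = wx if cur_w is None else cur_w + wx
            if new_w == 0.0:
                if cur_w is not None:
                    self._set_weight(keep, x, None, touched)
            else:
                self._set_weight(keep, x, new_w, touched)
        self.members[keep].extend(self.members.pop(gone))
        self._flush(touched)

    def run(self) -> list[list[int]]:
        heap, cur = self.heap, self.cur
        while heap:
            negp, _negw, u, v = heapq.heappop(heap)
            key = u * self.n + v if u < v else v * self.n + u
            if key not in self.icf:
                continue  # edge decided or contracted away
            p = -negp
            if p != cur[key]:
                self._set_prio(key, u, v)  # stale entry: reinsert current
                continue
            if self.icf[key] >= self.icp[key]:
                self._merge(u, v)
            else:
                self._forbid(u, v)
        return [sorted(mem) for mem in self.members.values()]


def cluster_reads(graph: SimilarityGraph,
                  config: ClusterEditingConfig | None = None) -> Clustering:
    """Partition reads into clusters via greedy cluster editing.

    Runs per connected component of the nonzero-edge graph; reads without
    any nonzero edge become singleton clusters.
    """
    cfg = config or ClusterEditingConfig()
    m = graph.n_nodes
    if m == 0:
        return Clustering(clusters=[], n_reads=0)
    if graph.n_edges == 0:
        return Clustering(clusters=[[u] for u in range(m)], n_reads=m)

    adj_mat = coo_matrix(
        (np.ones(graph.n_edges), (graph.us, graph.vs)), shape=(m, m)
    )
    n_comp, labels = connected_components(adj_mat, directed=False)
    clusters: list[list[int]] = []
    edge_comp = labels[graph.us]
    for comp in range(n_comp):
        nodes = np.flatnonzero(labels == comp)
        if nodes.size == 1:
            clusters.append([int(nodes[0])])
            continue
        if nodes.size > cfg.max_component_size:
            raise RuntimeError(
                f"connected component of {nodes.size} reads exceeds "
                f"max_component_size={cfg.max_component_size}"
            )
        local = {int(g): i for i, g in enumerate(nodes)}
        sel = edge_comp == comp
        edges = [
            (local[int(u)], local[int(v)], float(w))
            for u, v, w in zip(graph.us[sel], graph.vs[sel], graph.weights[sel])
        ]
        solver = _GreedySolver(nodes.size, edges,
                               by_weight=(cfg.tie_break == "weight"))
        for mem in solver.run():
            clusters.append([int(nodes[i]) for i in mem])
    clusters.sort(key=lambda c: c[0])
    logger.info("cluster editing: %d reads -> %d clusters", m, len(clusters))
    return Clustering(clusters=clusters, n_reads=m)


def editing_cost(graph: SimilarityGraph, clustering: Clustering) -> float:
    """Total cost of the edits implied by a clustering.

    Deleting a positive edge across clusters costs its weight; inserting a
    missing (negative) edge within a cluster costs its absolute weight.
    """
    assign = clustering.assignment()
    same = assign[graph.us] == assign[graph.vs]
    w = graph.weights
    return float(np.sum(np.where(same, np.maximum(0.0, -w), np.maximum(0.0, w))))
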