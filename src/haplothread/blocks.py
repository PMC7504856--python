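"""Phase-block segmentation of a threaded phasing.

Because distinct read clusters may or may not represent the same haplotype,
the phasing is cut wherever its continuation is not sufficiently certain.
Four sensitivity levels nest from permissive to conservative:

  1. cut only where consecutive variants share no covering read
     (the block definition used by connected-component based phasers),
  2. additionally cut where two or more threads change cluster
     (multi-switch: the continuation is ambiguous),
  3. (default) additionally cut where a collapsed cluster loses multiplicity
     and the co-resident threads entered it at different positions or from
     different predecessor clusters (separation cut: which thread leaves
     changes the result),
  4. additionally cut at every single thread-cluster change.

A single switching thread alone forces no cut below level 4: with k-1
threads staying put, the old cluster is linked to the new one by
elimination.  Cut positions are nested across levels by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import GAP, Phasing, Variant
from .threading import ClusterProfile, Threading

logger = logging.getLogger(__name__)

CUT_TYPES = ("no-connectivity", "single-switch", "multi-switch", "separation")


@dataclass
class Cut:
    position: int                  # cut between variants position-1 and position
    type: str
    involved: tuple[int, ...]      # thread indices interrupted by this cut


@dataclass
class CutSet:
    cuts: dict[int, Cut] = field(default_factory=dict)

    @property
    def positions(self) -> set[int]:
        return set(self.cuts)

    def add(self, position: int, type_: str, involved) -> None:
        self.cuts[position] = Cut(position=position, type=type_,
                                  involved=tuple(sorted(involved)))

    def __len__(self) -> int:
        return len(self.cuts)


def compute_cuts(threading: Threading, profile: ClusterProfile,
                 sensitivity: int = 3) -> CutSet:
    """Place block cuts on a threading at the given sensitivity level."""
    if sensitivity not in (1, 2, 3, 4):
        raise ValueError(f"unknown block-cut sensitivity {sensitivity!r}")
    k, n = threading.thread_clusters.shape
    tc = threading.thread_clusters
    cuts = CutSet()

    phased = [j for j in range(n) if threading.tuples[j] is not None]
    if not phased:
        return cuts
    # entry bookkeeping per thread: (entry position, predecessor cluster)
    entry: list[tuple[int, int | None]] = [(phased[0], None)] * k
    prev = phased[0]
    for j in phased[1:]:
        gap = j - prev > 1
        if gap or not profile.connected[j]:
            cuts.add(j, "no-connectivity", range(k))
            entry = [(j, None)] * k
            prev = j
            continue

        changed = [t for t in range(k) if tc[t, prev] != tc[t, j]]
        cut_type = None
        involved: tuple[int, ...] | range = ()
        if sensitivity >= 2 and len(changed) >= 2:
            cut_type, involved = "multi-switch", changed
        elif sensitivity >= 3 and changed:
            for c in set(tc[:, prev].tolist()):
                residents = [t for t in range(k) if tc[t, prev] == c]
                mult_next = int(np.sum(tc[:, j] == c))
                if (
                    len(residents) >= 2
                    and mult_next < len(residents)
                    and len({entry[t] for t in residents}) > 1
                ):
                    cut_type, involved = "separation", residents
                    break
        if cut_type is None and sensitivity >= 4 and changed:
            cut_type, involved = "single-switch", changed

        if cut_type is not None:
            cuts.add(j, cut_type, involved)
            entry = [(j, None)] * k
        else:
            for t in changed:
                entry[t] = (j, int(tc[t, prev]))
        prev = j
    return cuts


def assign_phase_sets(haplotypes: np.ndarray, cuts: CutSet,
                      variants: list[Variant] | None = None) -> Phasing:
    """Assemble a Phasing with PS and per-haplotype HS block identifiers.

    Every cut interrupts all haplotypes at the PS level (one phase set per
    variant, as representable in a VCF); at the HS level only the threads
    involved in the cut start a new haplotype block.  Block ids are the
    index of the first variant of the block.
    """
    haplotypes = np.asarray(haplotypes, dtype=np.int8)
    k, n = haplotypes.shape
    phase_set = np.full(n, GAP, dtype=np.int64)
    haplo_phase_set = np.full((k, n), GAP, dtype=np.int64)

    phased_mask = np.all(haplotypes != GAP, axis=0)
    cur_ps = None
    cur_hs = [None] * k
    for j in range(n):
        if not phased_mask[j]:
            cur_ps = None
            cur_hs = [None] * k
            continue
        cut = cuts.cuts.get(j)
        if cur_ps is None:
            cur_ps = j
            cur_hs = [j] * k
        elif cut is not None:
            cur_ps = j
            for t in cut.involved:
                cur_hs[t] = j
        phase_set[j] = cur_ps
        for t in range(k):
            haplo_phase_set[t, j] = cur_hs[t]

    return Phasing(
        haplotypes=np.where(phased_mask[None, :], haplotypes, GAP).astype(np.int8),
        phase_set=phase_set,
        haplo_phase_set=haplo_phase_set,
        variants=list(variants) if variants is not None else [],
    )
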