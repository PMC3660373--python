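"""Clustering of same-category anomalous pairs and breakpoint prediction.

Two pairs *i*, *j* of the same category (and chromosome/strand group)
support the same aberration when both their anchor coordinates agree within
a distance bound D::

    |x1_i - x1_j| <= D   and   |x2_i - x2_j| <= D,      D = UC - LC

(for a normal library D equals ``2 z_{1-alpha/2} sigma``).  Anchors are the
innermost, junction-proximal aligned coordinates: forward-read end and
reverse-read start (x+, x-) for opposite-strand categories; for same-strand
categories the innermost coordinate of each side, side roles fixed by
coordinate (or chromosome order, inter-chromosomally).

Clusters are the transitive closure (connected components) of this
relation, computed by union-find inside a coordinate-sorted sweep: after
sorting on the first anchor only pairs within D of each other on that axis
can be related, so the candidate-edge scan is near-linear.  Components are
independent of input order, and every pair belongs to at most one cluster.
Only clusters with support S >= 2 are emitted.

Each emitted cluster predicts two breakpoint intervals.  A side supported
by forward reads localises its junction in ``[max_i x+_i, min_i x+_i + UC)``
-- the junction cannot precede the last forward base, and the earliest pair
bounds how far it can sit downstream (the gap beyond any innermost anchor
is at most UC); a reverse-supported side mirrors this as
``(max_i x-_i - UC, min_i x-_i]``.  Widths shrink (weakly) as S grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .classify import (
    ANOMALOUS,
    OPPOSITE_STRAND,
    SAME_STRAND,
    Category,
    ReadPairRecord,
    pair_anchors,
)

MIN_SUPPORT = 2
#: one-sided Poisson tail below which a cluster's support is "special"
SPECIAL_SUPPORT_P = 1e-4


@dataclass
class Side:
    chrom: str
    strand: str  # strand of the reads anchoring this side
    anchors: np.ndarray  # rightmost aligned positions (exclusive ends)
    interval: Optional[tuple[int, int]] = None  # [lo, hi) predicted junction


@dataclass
class Cluster:
    category: Category
    sideA: Side  # lower (chrom, coordinate) side
    sideB: Side
    members: list = field(default_factory=list)  # ReadPairRecord
    cluster_id: Optional[str] = None
    q_tier: Optional[str] = None  # '1' | '2' | 'lower'
    support_tier: Optional[str] = None  # 'high' | 'medium' | 'low' | 'special'
    length_tier: Optional[str] = None  # 'high'|'medium'|'low'|'special'|'n/a'
    unreliable: bool = False  # the two predicted intervals overlap each other

    @property
    def S(self) -> int:
        return len(self.members)

    @property
    def chromA(self) -> str:
        return self.sideA.chrom

    @property
    def chromB(self) -> str:
        return self.sideB.chrom

    @property
    def bpA(self) -> tuple[int, int]:
        return self.sideA.interval

    @property
    def bpB(self) -> tuple[int, int]:
        return self.sideB.interval

    @property
    def sides(self) -> tuple[Side, Side]:
        return (self.sideA, self.sideB)

    def span(self) -> Optional[float]:
        """Distance between predicted interval midpoints (intra-chromosomal)."""
        if self.chromA != self.chromB or self.bpA is None or self.bpB is None:
            return None
        midA = (self.bpA[0] + self.bpA[1]) / 2
        midB = (self.bpB[0] + self.bpB[1]) / 2
        return abs(midB - midA)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            # deterministic root: keep the smaller index
            if rj < ri:
                ri, rj = rj, ri
            self.parent[rj] = ri


def _components(a1: np.ndarray, a2: np.ndarray, D: float) -> list[list[int]]:
    """Connected components of the |da1|<=D and |da2|<=D relation."""
    n = len(a1)
    order = np.lexsort((a2, a1))
    uf = _UnionFind(n)
    s1, s2 = a1[order], a2[order]
    for i in range(n):
        for j in range(i + 1, n):
            if s1[j] - s1[i] > D:
                break
            if abs(s2[j] - s2[i]) <= D:
                uf.union(int(order[i]), int(order[j]))
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(uf.find(i), []).append(i)
    # deterministic ordering: by smallest member anchor, then read name
    out = []
    for root in sorted(comps, key=lambda r: (a1[comps[r][0]], r)):
        out.append(sorted(comps[root], key=lambda i: (a1[i], a2[i])))
    return out


def _build_cluster(cat: Category, key, members: list[ReadPairRecord],
                   a1: Sequence[int], a2: Sequence[int]) -> Cluster:
    a1 = np.asarray(a1)
    a2 = np.asarray(a2)
    if cat in OPPOSITE_STRAND:
        _, chrom_fwd, chrom_rev = key
        fwd = Side(chrom_fwd, "+", a1)
        rev = Side(chrom_rev, "-", a2)
        if chrom_fwd == chrom_rev:
            # side A = lower-coordinate side
            sideA, sideB = (fwd, rev) if a1.mean() <= a2.mean() else (rev, fwd)
        else:
            sideA, sideB = (fwd, rev) if chrom_fwd < chrom_rev else (rev, fwd)
    else:
        _, strand, chromA, chromB = key
        sideA = Side(chromA, strand, a1)
        sideB = Side(chromB, strand, a2)
    return Cluster(category=cat, sideA=sideA, sideB=sideB, members=list(members))


def _cluster_group(cat: Category, key, group: list, D: float,
                   min_support: int) -> list[Cluster]:
    members = [g[0] for g in group]
    a1 = np.array([g[1] for g in group], dtype=float)
    a2 = np.array([g[2] for g in group], dtype=float)
    out = []
    for comp in _components(a1, a2, D):
        if len(comp) < min_support:
            continue
        out.append(_build_cluster(cat, key,
                                  [members[i] for i in comp],
                                  a1[comp].astype(int), a2[comp].astype(int)))
    return out


def _cluster_pairs(pairs: Iterable[ReadPairRecord], allowed, model,
                   D: Optional[float], min_support: int) -> list[Cluster]:
    if D is None:
        D = model.D
    groups: dict = {}
    for rp in pairs:
        if rp.category not in allowed:
            raise ValueError(
                f"pair category {rp.category} not allowed here (expected one of {allowed})"
            )
        key, x1, x2 = pair_anchors(rp)
        groups.setdefault(key, []).append((rp, x1, x2))
    clusters = []
    for key in sorted(groups, key=str):
        clusters.extend(_cluster_group(key[0], key, groups[key], D, min_support))
    return clusters


def cluster_opposite_strand(
    pairs: Iterable[ReadPairRecord],
    model,
    D: Optional[float] = None,
    min_support: int = MIN_SUPPORT,
) -> list[Cluster]:
    """Cluster distance-, order- or chrpos-pairs (one read per strand)."""
    return _cluster_pairs(pairs, OPPOSITE_STRAND, model, D, min_support)


def cluster_same_strand(
    pairs: Iterable[ReadPairRecord],
    model,
    D: Optional[float] = None,
    min_support: int = MIN_SUPPORT,
) -> list[Cluster]:
    """Cluster ori- or chrposori-pairs (both reads on one strand).

    Forward-forward pairs cluster among themselves and reverse-reverse pairs
    likewise; an inversion therefore leaves one cluster of each."""
    return _cluster_pairs(pairs, SAME_STRAND, model, D, min_support)


def cluster_anomalous(
    pairs: Iterable[ReadPairRecord],
    model,
    D: Optional[float] = None,
    min_support: int = MIN_SUPPORT,
) -> list[Cluster]:
    """Cluster a mixed stream of anomalous pairs, category by category."""
    opp = [p for p in pairs if p.category in OPPOSITE_STRAND]
    same = [p for p in pairs if p.category in SAME_STRAND]
    return (cluster_opposite_strand(opp, model, D, min_support) if opp else []) + (
        cluster_same_strand(same, model, D, min_support) if same else []
    )


def predict_breakpoints(
    cluster: Cluster,
    model,
    chrom_lengths: Optional[dict] = None,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Predict the two junction intervals of a cluster (S >= 2 required).

    Forward-supported side: ``[max x+, min x+ + UC)``; reverse-supported
    side: ``(max x- - UC, min x-]`` stored half-open as
    ``[max x- - UC + 1, min x- + 1)``.  Intervals are clipped to chromosome
    bounds, and the cluster is flagged unreliable when its two intervals
    overlap each other (the junctions are then not separable).
    """
    if cluster.S == 0:
        raise ValueError("cannot predict breakpoints of an empty cluster")
    UC = int(round(model.UC))
    for side in cluster.sides:
        a = side.anchors
        amax, amin = int(a.max()), int(a.min())
        if side.strand == "+":
            lo, hi = amax, amin + UC  # junction right of the forward reads
        else:
            lo, hi = amax - UC + 1, amin + 1  # junction left of the reverse reads
        if chrom_lengths and side.chrom in chrom_lengths:
            L = chrom_lengths[side.chrom]
            lo, hi = max(0, lo), min(L, hi)
        else:
            lo = max(0, lo)
        if hi <= lo:  # fully degenerate after clipping
            hi = lo + 1
        side.interval = (lo, hi)
    a, b = cluster.sideA.interval, cluster.sideB.interval
    cluster.unreliable = (
        cluster.chromA == cluster.chromB and a[0] < b[1] and b[0] < a[1]
    )
    return cluster.sideA.interval, cluster.sideB.interval


def annotate_confidence(
    cluster: Cluster,
    mean_coverage: float,
    q_thresholds: tuple[float, float] = (30.0, 20.0),
) -> Cluster:
    """Attach the confidence tiers used to stratify validation reliability.

    * support tier by S: special when S is significantly larger than the
      mean sequence coverage (one-sided Poisson tail < 1e-4), else
      high [10-50), medium [5-10), low below 5 (emitted clusters have S>=2).
    * quality tier: '1' if at least one member pair has both reads at
      Q >= 30 (>= 99.9% base-call accuracy), '2' for Q >= 20 (99%), else
      'lower'.
    * length tier (intra-chromosomal categories only): special >= 1 Mb,
      high [1 kb, 1 Mb), medium [500 bp, 1 kb), low < 500 bp; 'n/a' for
      chrpos/chrposori clusters, whose sides live on different chromosomes.
    """
    S = cluster.S
    if mean_coverage > 0 and stats.poisson.sf(S - 1, mean_coverage) < SPECIAL_SUPPORT_P:
        cluster.support_tier = "special"
    elif S >= 10:
        cluster.support_tier = "high"
    elif S >= 5:
        cluster.support_tier = "medium"
    else:
        cluster.support_tier = "low"

    q1, q2 = q_thresholds
    best = max(rp.pair_q for rp in cluster.members) if cluster.members else 0
    cluster.q_tier = "1" if best >= q1 else ("2" if best >= q2 else "lower")

    if cluster.category in (Category.CHRPOS, Category.CHRPOSORI):
        cluster.length_tier = "n/a"
    else:
        span = cluster.span()
        if span is None:
            cluster.length_tier = "n/a"
        elif span >= 1_000_000:
            cluster.length_tier = "special"
        elif span >= 1_000:
            cluster.length_tier = "high"
        elif span >= 500:
            cluster.length_tier = "medium"
        else:
            cluster.length_tier = "low"
    return cluster


def assign_ids(clusters: list[Cluster]) -> list[Cluster]:
    """Stable, sorted cluster ids (category, then side-A coordinates)."""
    clusters.sort(
        key=lambda c: (c.category.value, c.chromA, c.bpA or (0, 0), c.chromB, c.bpB or (0, 0))
    )
    for i, c in enumerate(clusters):
        c.cluster_id = f"{c.category.value.lower()}_{i:05d}"
    return clusters
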