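"""Combining read-pair clusters with depth segments into SV calls.

The caller distinguishes eleven combinatorial cases, collapsed to five
reported types.  Unbalanced cases require depth support over the affected
region; balanced cases require its absence:

====================  ==========================================  =========
class                 evidence                                    depth
====================  ==========================================  =========
DELETION              distance cluster                            LOSS
DUP_TANDEM            order cluster                               GAIN
GAIN_INTRA            distance + order cluster, one shared locus  GAIN
GAIN_INTRA_INV        fwd-ori + rev-ori cluster, one shared locus GAIN
GAIN_INTER(_INV)      two chrpos(ori) clusters, one shared locus  GAIN
INV                   fwd-ori + rev-ori, both loci shared         NEUTRAL
TRANS_INTRA           two distance + one order cluster, triangle  NEUTRAL
TRANS_INTRA_INV       distance + fwd-ori + rev-ori, triangle      NEUTRAL
TRANS_INTER(_INV)     distance + two chrpos(ori), triangle        NEUTRAL
====================  ==========================================  =========

Multi-cluster combinations are matched first (greedily by descending total
support), because a distance cluster that participates in a copy- or
cut-paste event must not be read as a plain deletion.  Distance clusters
left over without depth loss become PUTATIVE_DELETION; any other leftover
cluster becomes UNDEFINED and is routed to the repeat filter.  For copy and
cut events the call records both the source (copied/moved) region and the
insertion point.

"Equal" breakpoints are realised as interval overlap of the predicted
junction ranges (optionally padded by a tolerance): the prediction
intervals already encode the localisation uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np

from .classify import Category, ReadPairRecord, pair_anchors
from .cluster import Cluster
from .depth import DepthSegment

REPORTED_TYPE = {
    "DELETION": "deletion",
    "DUP_TANDEM": "gain",
    "GAIN_INTRA": "gain",
    "GAIN_INTRA_INV": "gain",
    "GAIN_INTER": "gain",
    "GAIN_INTER_INV": "gain",
    "INV": "inversion",
    "TRANS_INTRA": "intra_translocation",
    "TRANS_INTRA_INV": "intra_translocation",
    "TRANS_INTER": "inter_translocation",
    "TRANS_INTER_INV": "inter_translocation",
    "PUTATIVE_DELETION": "putative",
    "UNDEFINED": "undefined",
}


@dataclass
class SVCall:
    sv_class: str
    source_chrom: Optional[str] = None
    source_interval: Optional[tuple[int, int]] = None
    insertion_chrom: Optional[str] = None
    insertion_interval: Optional[tuple[int, int]] = None
    orientation: Optional[str] = None  # 'direct' | 'inverted'
    clusters: list = field(default_factory=list)
    rd_state: Optional[str] = None
    somatic: Optional[bool] = None
    flags: list = field(default_factory=list)
    te_identities: list = field(default_factory=list)

    @property
    def reported_type(self) -> str:
        return REPORTED_TYPE[self.sv_class]

    @property
    def defined(self) -> bool:
        """True when supported by depth or by a cluster combination; only
        undefined/putative calls are eligible for repeat filtering."""
        return self.sv_class not in ("PUTATIVE_DELETION", "UNDEFINED")

    @property
    def support(self) -> int:
        return sum(c.S for c in self.clusters)

    @property
    def cluster_ids(self) -> list[str]:
        return [c.cluster_id or "?" for c in self.clusters]

    @property
    def breakpoint_intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for c in self.clusters:
            for side in c.sides:
                if side.interval is not None:
                    out.append((side.chrom, side.interval[0], side.interval[1]))
        return out


def match_breakpoints(a: tuple[int, int], b: tuple[int, int], tolerance: int = 0) -> bool:
    """True iff the two [lo, hi) intervals overlap after symmetric padding."""
    return a[0] - tolerance < b[1] + tolerance and b[0] - tolerance < a[1] + tolerance


def _sides_overlap(s1, s2, tol: int) -> bool:
    return s1.chrom == s2.chrom and match_breakpoints(s1.interval, s2.interval, tol)


def _locus(s1, s2) -> tuple[str, int, int]:
    """Merged junction locus of two matched sides (intersection, or the
    1-bp midpoint of the gap when they only meet under tolerance)."""
    lo = max(s1.interval[0], s2.interval[0])
    hi = min(s1.interval[1], s2.interval[1])
    if hi <= lo:
        mid = (lo + hi) // 2
        lo, hi = mid, mid + 1
    return (s1.chrom, lo, hi)


class RdIndex:
    """Fraction-of-region depth-state queries over the segment calls."""

    def __init__(self, segments: Sequence[DepthSegment], window_size: int,
                 min_windows: int = 3, frac: float = 0.5):
        self.window_size = window_size
        self.min_len = min_windows * window_size
        self.frac = frac
        self.by_chrom: dict[str, list[DepthSegment]] = {}
        for seg in segments:
            self.by_chrom.setdefault(seg.chrom, []).append(seg)
        for segs in self.by_chrom.values():
            segs.sort(key=lambda s: s.start)

    def state_fractions(self, chrom: str, lo: int, hi: int) -> dict[str, float]:
        """bp-weighted state fractions over the part of [lo, hi) covered by
        segments (masked gaps are ignored)."""
        cov = {"GAIN": 0, "LOSS": 0, "NEUTRAL": 0}
        for seg in self.by_chrom.get(chrom, ()):
            o = min(hi, seg.end) - max(lo, seg.start)
            if o > 0:
                cov[seg.state] += o
        total = sum(cov.values())
        if total == 0:
            return {k: 0.0 for k in cov}
        return {k: v / total for k, v in cov.items()}

    def supports(self, chrom: str, lo: int, hi: int, state: str) -> Optional[bool]:
        """True/False when the region is long enough to judge; None when the
        region is shorter than the minimum window span (depth undefined at
        sub-window scale)."""
        if hi - lo < self.min_len:
            return None
        return self.state_fractions(chrom, lo, hi)[state] >= self.frac

    def majority_state(self, chrom: str, lo: int, hi: int) -> str:
        fr = self.state_fractions(chrom, lo, hi)
        return max(fr, key=lambda k: (fr[k], k))


def _triangle(c1: Cluster, c2: Cluster, c3: Cluster, tol: int):
    """Side assignment forming a three-locus triangle, or None.

    Each cluster contributes its two sides; a valid combination pairs every
    side with exactly one side of another cluster: loci (c1~c2), (c1~c3),
    (c2~c3)."""
    for i in (0, 1):
        for j in (0, 1):
            if not _sides_overlap(c1.sides[i], c2.sides[j], tol):
                continue
            for k in (0, 1):
                if not _sides_overlap(c1.sides[1 - i], c3.sides[k], tol):
                    continue
                if not _sides_overlap(c2.sides[1 - j], c3.sides[1 - k], tol):
                    continue
                return i, j, k
    return None


def _share_pattern(c1: Cluster, c2: Cluster, tol: int):
    """('both', i, j) when the clusters match on both sides, ('one', i, j)
    when exactly one side pair (i, j) matches, else None."""
    matches = [
        (i, j)
        for i in (0, 1)
        for j in (0, 1)
        if _sides_overlap(c1.sides[i], c2.sides[j], tol)
    ]
    for i, j in matches:
        if _sides_overlap(c1.sides[1 - i], c2.sides[1 - j], tol):
            return ("both", i, j)
    if len(matches) == 1:
        return ("one", *matches[0])
    return None


def _outer_span(*sides) -> tuple[str, int, int]:
    chrom = sides[0].chrom
    lo = min(s.interval[0] for s in sides)
    hi = max(s.interval[1] for s in sides)
    return chrom, lo, hi


def _is_balanced_ok(rd: RdIndex, chrom: str, lo: int, hi: int) -> bool:
    """Balanced calls must not sit on depth gain or loss support."""
    return not rd.supports(chrom, lo, hi, "GAIN") and not rd.supports(chrom, lo, hi, "LOSS")


def define_svs(
    clusters: Sequence[Cluster],
    segments: Sequence[DepthSegment],
    window_size: int = 100,
    tolerance: int = 0,
    rd_fraction: float = 0.5,
    min_rd_windows: int = 3,
) -> list[SVCall]:
    """Apply the combination rule table.  Every input cluster ends up in
    exactly one call (possibly PUTATIVE_DELETION or UNDEFINED)."""
    rd = RdIndex(segments, window_size, min_windows=min_rd_windows, frac=rd_fraction)
    calls: list[SVCall] = []
    used: set[int] = set()

    def free(*cs) -> bool:
        return all(id(c) not in used for c in cs)

    def take(call: SVCall) -> None:
        for c in call.clusters:
            used.add(id(c))
        calls.append(call)

    reliable = [c for c in clusters if not c.unreliable]
    for c in clusters:
        if c.unreliable:
            take(SVCall("UNDEFINED", source_chrom=c.chromA,
                        source_interval=c.bpA, clusters=[c],
                        rd_state=None, flags=["unreliable_overlapping_breakpoints"]))

    by_cat: dict[Category, list[Cluster]] = {}
    for c in reliable:
        by_cat.setdefault(c.category, []).append(c)
    dist = by_cat.get(Category.DISTANCE, [])
    order = by_cat.get(Category.ORDER, [])
    ori_f = [c for c in by_cat.get(Category.ORI, []) if c.sideA.strand == "+"]
    ori_r = [c for c in by_cat.get(Category.ORI, []) if c.sideA.strand == "-"]
    chrpos = by_cat.get(Category.CHRPOS, [])
    chrposori = by_cat.get(Category.CHRPOSORI, [])

    candidates: list[tuple[int, int, str, tuple]] = []  # (rank, -S, key, payload)

    def add(rank: int, payload: tuple, *cs: Cluster) -> None:
        key = "|".join(sorted(c.cluster_id or str(id(c)) for c in cs))
        candidates.append((rank, -sum(c.S for c in cs), key, payload))

    # ---- triples (balanced translocations) --------------------------------
    for d1, d2 in combinations(dist, 2):
        if d1.chromA != d2.chromA or d1.chromA != d1.chromB:
            continue
        for o in order:
            if o.chromA != d1.chromA:
                continue
            if _triangle(d1, d2, o, tolerance) is None:
                continue
            src = min((d1, d2), key=lambda c: (c.span() or 0, c.cluster_id or ""))
            other = d2 if src is d1 else d1
            tri = _triangle(src, other, o, tolerance)
            if tri is None:
                continue
            i, j, k = tri
            ins = _locus(other.sides[1 - j], o.sides[1 - k])
            chrom, lo, hi = _outer_span(*src.sides)
            if not _is_balanced_ok(rd, chrom, lo, hi):
                continue
            add(0, ("TRANS_INTRA", chrom, (lo, hi), ins, "direct", (d1, d2, o)), d1, d2, o)

    for d in dist:
        if d.chromA != d.chromB:
            continue
        for f in ori_f:
            if f.chromA != d.chromA:
                continue
            for r in ori_r:
                if r.chromA != d.chromA:
                    continue
                tri = _triangle(d, f, r, tolerance)
                if tri is None:
                    continue
                i, j, k = tri
                ins = _locus(f.sides[1 - j], r.sides[1 - k])
                chrom, lo, hi = _outer_span(*d.sides)
                if not _is_balanced_ok(rd, chrom, lo, hi):
                    continue
                add(0, ("TRANS_INTRA_INV", chrom, (lo, hi), ins, "inverted", (d, f, r)),
                    d, f, r)

    for inter_cat, cls, orient in ((chrpos, "TRANS_INTER", "direct"),
                                   (chrposori, "TRANS_INTER_INV", "inverted")):
        for d in dist:
            if d.chromA != d.chromB:
                continue
            for c1, c2 in combinations(inter_cat, 2):
                tri = _triangle(d, c1, c2, tolerance)
                if tri is None:
                    continue
                i, j, k = tri
                ins = _locus(c1.sides[1 - j], c2.sides[1 - k])
                if ins[0] == d.chromA:
                    continue  # insertion must land on the other chromosome
                chrom, lo, hi = _outer_span(*d.sides)
                if not _is_balanced_ok(rd, chrom, lo, hi):
                    continue
                add(0, (cls, chrom, (lo, hi), ins, orient, (d, c1, c2)), d, c1, c2)

    # ---- pairs (copy-number gains with an insertion point) ----------------
    def gain_pair(c1: Cluster, c2: Cluster, cls: str, orient: str,
                  require_other_chrom: bool) -> None:
        pat = _share_pattern(c1, c2, tolerance)
        if pat is None or pat[0] != "one":
            return
        _, i, j = pat
        u1, u2 = c1.sides[1 - i], c2.sides[1 - j]
        if u1.chrom != u2.chrom:
            return
        ins = _locus(c1.sides[i], c2.sides[j])
        if require_other_chrom and ins[0] == u1.chrom:
            return
        if not require_other_chrom and ins[0] != u1.chrom:
            return
        chrom, lo, hi = _outer_span(u1, u2)
        if rd.supports(chrom, lo, hi, "GAIN"):
            add(1, (cls, chrom, (lo, hi), ins, orient, (c1, c2)), c1, c2)

    for d in dist:
        if d.chromA != d.chromB:
            continue
        for o in order:
            if o.chromA == d.chromA:
                gain_pair(d, o, "GAIN_INTRA", "direct", False)
    for f in ori_f:
        for r in ori_r:
            if f.chromA == r.chromA:
                gain_pair(f, r, "GAIN_INTRA_INV", "inverted", False)
    for group, cls in ((chrpos, "GAIN_INTER"), (chrposori, "GAIN_INTER_INV")):
        orient = "inverted" if cls.endswith("_INV") else "direct"
        for c1, c2 in combinations(group, 2):
            gain_pair(c1, c2, cls, orient, True)

    # ---- inversions -------------------------------------------------------
    for f in ori_f:
        for r in ori_r:
            if f.chromA != r.chromA or f.chromA != f.chromB:
                continue
            pat = _share_pattern(f, r, tolerance)
            if pat is None or pat[0] != "both":
                continue
            chrom, lo, hi = _outer_span(*f.sides, *r.sides)
            if not _is_balanced_ok(rd, chrom, lo, hi):
                continue
            add(2, ("INV", chrom, (lo, hi), None, "inverted", (f, r)), f, r)

    # ---- greedy acceptance ------------------------------------------------
    for rank, negS, key, payload in sorted(candidates, key=lambda t: t[:3]):
        cls, chrom, interval, ins, orient, cs = payload
        if not free(*cs):
            continue
        take(
            SVCall(
                cls,
                source_chrom=chrom,
                source_interval=interval,
                insertion_chrom=ins[0] if ins else None,
                insertion_interval=(ins[1], ins[2]) if ins else None,
                orientation=orient,
                clusters=list(cs),
                rd_state=rd.majority_state(chrom, *interval),
            )
        )

    # ---- single-cluster rules and leftovers -------------------------------
    for c in reliable:
        if not free(c):
            continue
        if c.category is Category.DISTANCE and c.chromA == c.chromB:
            chrom, lo, hi = _outer_span(*c.sides)
            if rd.supports(chrom, lo, hi, "LOSS"):
                take(SVCall("DELETION", source_chrom=chrom, source_interval=(lo, hi),
                            clusters=[c], rd_state="LOSS"))
            else:
                take(SVCall("PUTATIVE_DELETION", source_chrom=chrom,
                            source_interval=(lo, hi), clusters=[c],
                            rd_state=rd.majority_state(chrom, lo, hi)))
        elif c.category is Category.ORDER and c.chromA == c.chromB:
            chrom, lo, hi = _outer_span(*c.sides)
            if rd.supports(chrom, lo, hi, "GAIN"):
                take(SVCall("DUP_TANDEM", source_chrom=chrom, source_interval=(lo, hi),
                            clusters=[c], rd_state="GAIN"))
            else:
                take(SVCall("UNDEFINED", source_chrom=chrom, source_interval=(lo, hi),
                            clusters=[c], rd_state=rd.majority_state(chrom, lo, hi)))
        else:
            take(SVCall("UNDEFINED", source_chrom=c.chromA, source_interval=c.bpA,
                        clusters=[c]))
    return calls


# ---------------------------------------------------------------------------
# somatic subtraction


class _PairIndex:
    """Anchor lookup over the raw anomalous pairs of the matched normal."""

    def __init__(self, pairs: Iterable[ReadPairRecord]):
        tmp: dict = {}
        for rp in pairs:
            key, a1, a2 = pair_anchors(rp)
            tmp.setdefault(key, []).append((a1, a2))
        self.index = {}
        for key, items in tmp.items():
            items.sort()
            a1 = np.array([i[0] for i in items], dtype=np.int64)
            a2 = np.array([i[1] for i in items], dtype=np.int64)
            self.index[key] = (a1, a2)

    def near(self, key, a1: int, a2: int, D: float) -> bool:
        entry = self.index.get(key)
        if entry is None:
            return False
        xs, ys = entry
        lo = int(np.searchsorted(xs, a1 - D, side="left"))
        hi = int(np.searchsorted(xs, a1 + D, side="right"))
        return bool(np.any(np.abs(ys[lo:hi] - a2) <= D))


def subtract_shared(
    tumour_clusters: Sequence[Cluster],
    normal_pairs: Iterable[ReadPairRecord],
    model,
    D: Optional[float] = None,
) -> list[Cluster]:
    """Remove tumour clusters shared with the matched normal.

    A cluster is germline evidence -- and removed -- as soon as a single
    anomalous normal pair of the same category would have co-clustered with
    any of its members under the clustering distance bound (deliberately
    stricter than requiring a normal cluster of S >= 2).  Survivors are the
    somatic clusters.
    """
    if model is None and D is None:
        raise ValueError("need an insert model or an explicit distance bound")
    if D is None:
        D = model.D
    idx = _PairIndex(normal_pairs)
    somatic = []
    for cl in tumour_clusters:
        shared = False
        for rp in cl.members:
            key, a1, a2 = pair_anchors(rp)
            if idx.near(key, a1, a2, D):
                shared = True
                break
        if not shared:
            somatic.append(cl)
    return somatic
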