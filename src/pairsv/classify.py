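"""Read-pair triage and anomaly classification.

Every mapped read pair is assigned to exactly one category based on
chromosome equality, strand configuration, mapping order and insert length
relative to the library cut-offs [LC, UC]:

* ``CONCORDANT``       -- same chromosome, leftmost read forward / rightmost
  reverse, LC <= l <= UC.
* ``DISTANCE``         -- same configuration but l > UC (stretched insert;
  deletion-like, but also part of copy/cut-paste signatures).
* ``INSERT_DISCARDED`` -- same configuration but l < LC.  Such pairs indicate
  small insertions; their resolution is bounded by the library spread, so
  they are counted and dropped rather than clustered.
* ``ORDER``            -- same chromosome, leftmost read reverse / rightmost
  forward (wrong order).
* ``ORI``              -- same chromosome, both reads on the same strand.
* ``CHRPOS``           -- different chromosomes, opposite strands.
* ``CHRPOSORI``        -- different chromosomes, same strand.

One-end-anchored (``ONE_END``) and fully unmapped (``ORPHAN``) pairs are
kept apart at triage time; the former still contribute to read depth.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional


class Category(str, Enum):
    CONCORDANT = "CONCORDANT"
    DISTANCE = "DISTANCE"
    ORDER = "ORDER"
    ORI = "ORI"
    CHRPOS = "CHRPOS"
    CHRPOSORI = "CHRPOSORI"
    INSERT_DISCARDED = "INSERT_DISCARDED"
    ONE_END = "ONE_END"
    ORPHAN = "ORPHAN"

    def __str__(self) -> str:  # tidy TSV output
        return self.value


#: categories streamed to the clusterer
ANOMALOUS = (
    Category.DISTANCE,
    Category.ORDER,
    Category.ORI,
    Category.CHRPOS,
    Category.CHRPOSORI,
)

#: opposite-strand anomaly categories (one read +, one read -)
OPPOSITE_STRAND = (Category.DISTANCE, Category.ORDER, Category.CHRPOS)
#: same-strand anomaly categories
SAME_STRAND = (Category.ORI, Category.CHRPOSORI)


@dataclass(frozen=True)
class ReadAlignment:
    """One aligned (or unaligned) read of a pair."""

    name: str
    chrom: Optional[str]
    start: int  # 0-based
    end: int  # exclusive
    strand: str  # '+' or '-'
    mapq: int = 60
    baseq: float = 40.0  # mean base quality of the read
    mapped: bool = True
    read1: bool = True
    read_group: Optional[str] = None


@dataclass
class ReadPairRecord:
    """A jointly considered pair.  ``read_a`` is the read with the smaller
    (chrom, start); for pairs with unmapped members the mapped read (if any)
    is ``read_a``."""

    name: str
    read_a: ReadAlignment
    read_b: ReadAlignment
    category: Optional[Category] = None
    l: Optional[int] = None  # insert length for category-(1) configurations
    read_group: Optional[str] = None

    @property
    def pair_q(self) -> float:
        """Pair quality: worst read's min(mapping quality, mean base quality)."""
        return min(
            min(self.read_a.mapq, self.read_a.baseq),
            min(self.read_b.mapq, self.read_b.baseq),
        )

    @property
    def min_mapq(self) -> int:
        return min(self.read_a.mapq, self.read_b.mapq)


def triage_pair(r1: ReadAlignment, r2: ReadAlignment) -> ReadPairRecord:
    """Sort a raw pair into mapped / one-end / orphan and normalise read order.

    Raises ``ValueError`` if the two records do not share a read name.
    """
    if r1.name != r2.name:
        raise ValueError(f"mismatched read names: {r1.name!r} vs {r2.name!r}")
    rg = r1.read_group or r2.read_group
    if r1.mapped and r2.mapped:
        a, b = sorted((r1, r2), key=lambda r: (r.chrom, r.start, r.strand == "-"))
        return ReadPairRecord(r1.name, a, b, read_group=rg)
    if r1.mapped or r2.mapped:
        a, b = (r1, r2) if r1.mapped else (r2, r1)
        return ReadPairRecord(r1.name, a, b, category=Category.ONE_END, read_group=rg)
    return ReadPairRecord(r1.name, r1, r2, category=Category.ORPHAN, read_group=rg)


def _oriented(rp: ReadPairRecord, library_type: str) -> tuple[str, str]:
    """Strands of (read_a, read_b) after the library-convention switch.

    Mate-pair (jumping) libraries produce the mirror strand layout of
    paired-end data; flipping both strands reduces them to one convention.
    """
    sa, sb = rp.read_a.strand, rp.read_b.strand
    if library_type == "mate_pair":
        flip = {"+": "-", "-": "+"}
        sa, sb = flip[sa], flip[sb]
    return sa, sb


def classify_pair(
    rp: ReadPairRecord,
    model,
    library_type: str = "paired_end",
) -> Category:
    """Assign a mapped pair to its (unique) category.

    ``model`` provides the ``LC``/``UC`` cut-offs (see
    :class:`pairsv.insert_size.InsertSizeModel`).  Total over all mapped-pair
    configurations.  Records the category (and ``l`` where defined) on ``rp``.
    """
    if rp.category in (Category.ONE_END, Category.ORPHAN):
        return rp.category
    a, b = rp.read_a, rp.read_b
    sa, sb = _oriented(rp, library_type)
    if a.chrom != b.chrom:
        cat = Category.CHRPOSORI if sa == sb else Category.CHRPOS
    elif sa == sb:
        cat = Category.ORI
    else:
        # read_a is leftmost (ties already resolved toward "right order" by
        # the triage sort, which puts the forward read first at equal starts)
        if sa == "+":
            l = b.start - a.end  # innermost gap
            rp.l = l
            if l > model.UC:
                cat = Category.DISTANCE
            elif l < model.LC:
                cat = Category.INSERT_DISCARDED
            else:
                cat = Category.CONCORDANT
        else:
            cat = Category.ORDER
    rp.category = cat
    return cat


def classify_pairs(
    pairs: Iterable[ReadPairRecord],
    models,
    library_type: str = "paired_end",
    mapq_floor: int = 1,
) -> Iterator[ReadPairRecord]:
    """Classify a stream of triaged pairs.

    Pairs where either read falls below ``mapq_floor`` are dropped before
    classification (multi-mappers reported at mapq 0 otherwise seed spurious
    anomaly categories).  ONE_END / ORPHAN records pass through unchanged.
    """
    for rp in pairs:
        if rp.category in (Category.ONE_END, Category.ORPHAN):
            yield rp
            continue
        if rp.min_mapq < mapq_floor:
            continue
        classify_pair(rp, models.for_pair(rp), library_type)
        yield rp


def _innermost(read: ReadAlignment) -> int:
    """Junction-proximal coordinate of a read: a forward read points
    rightward (its end is innermost), a reverse read points leftward."""
    return read.end if read.strand == "+" else read.start


def pair_anchors(rp: ReadPairRecord) -> tuple[tuple, int, int]:
    """Clustering key and the two anchor coordinates of an anomalous pair.

    Anchors are the innermost (junction-proximal) aligned coordinates: for
    opposite-strand categories ``(x+, x-)`` = (forward read end, reverse
    read start); for same-strand categories the side roles are fixed by
    coordinate (lower read = side 1) or, inter-chromosomally, by chromosome
    order.  The key separates groups that can never co-cluster: category,
    the chromosomes holding each anchor and (same-strand only) the shared
    strand.
    """
    cat = rp.category
    a, b = rp.read_a, rp.read_b
    if cat in OPPOSITE_STRAND:
        fwd, rev = (a, b) if a.strand == "+" else (b, a)
        key = (cat, fwd.chrom, rev.chrom)
        return key, fwd.end, rev.start
    if cat in SAME_STRAND:
        key = (cat, a.strand, a.chrom, b.chrom)
        return key, _innermost(a), _innermost(b)
    raise ValueError(f"pair is not anomalous: {cat}")
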