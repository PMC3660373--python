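"""Synthetic genomes, rearranged donors and paired-read alignments.

Everything downstream of alignment is testable from this module alone: a
random reference is generated with a controllable GC profile, structural
variants of all eleven combinatorial classes are applied to produce a donor
genome with exactly known junctions, and read pairs are drawn uniformly
from the donor and emitted directly in reference coordinates through the
donor->reference block map.  No aligner runs; truth is exact by
construction.  Reads that straddle a junction are emitted unmapped, which
is what a strict unique-alignment mapper does with them (only split-read
methods recover those).

Supported classes and their discordant-pair signatures (junction-spanning
pairs only; f = forward-anchored, r = reverse-anchored):

========================  ====================================================
DEL                       one distance cluster + depth loss
DUP_TANDEM                one order cluster + depth gain
GAIN_INTRA                distance + order cluster + gain over the copy
GAIN_INTRA_INV            f-ori + r-ori cluster + gain over the copy
GAIN_INTER / _INV         two chrpos / chrposori clusters + gain over the copy
INV                       f-ori + r-ori cluster, matching junctions, neutral
TRANS_INTRA               two distance + one order cluster, neutral
TRANS_INTRA_INV           one distance + f-ori + r-ori cluster, neutral
TRANS_INTER / _INV        distance + two chrpos / chrposori clusters, neutral
========================  ====================================================

The library is modelled as paired-end: insert length Normal(mean, sd),
truncated below at twice the read length; fragments sampled uniformly along
the donor; base qualities uniform at a configurable phred value with an
optional low-quality fraction to exercise quality-tier logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .classify import Category, ReadAlignment

SV_CLASSES = (
    "DEL",
    "DUP_TANDEM",
    "GAIN_INTRA",
    "GAIN_INTRA_INV",
    "GAIN_INTER",
    "GAIN_INTER_INV",
    "INV",
    "TRANS_INTRA",
    "TRANS_INTRA_INV",
    "TRANS_INTER",
    "TRANS_INTER_INV",
)

#: classes that move or copy material and therefore carry an insertion point
NEEDS_INSERT = (
    "GAIN_INTRA",
    "GAIN_INTRA_INV",
    "GAIN_INTER",
    "GAIN_INTER_INV",
    "TRANS_INTRA",
    "TRANS_INTRA_INV",
    "TRANS_INTER",
    "TRANS_INTER_INV",
)

#: expected anomaly categories of junction-spanning pairs, per class
EXPECTED_CATEGORIES = {
    "DEL": [Category.DISTANCE],
    "DUP_TANDEM": [Category.ORDER],
    "GAIN_INTRA": [Category.DISTANCE, Category.ORDER],
    "GAIN_INTRA_INV": [Category.ORI, Category.ORI],
    "GAIN_INTER": [Category.CHRPOS, Category.CHRPOS],
    "GAIN_INTER_INV": [Category.CHRPOSORI, Category.CHRPOSORI],
    "INV": [Category.ORI, Category.ORI],
    "TRANS_INTRA": [Category.DISTANCE, Category.DISTANCE, Category.ORDER],
    "TRANS_INTRA_INV": [Category.DISTANCE, Category.ORI, Category.ORI],
    "TRANS_INTER": [Category.DISTANCE, Category.CHRPOS, Category.CHRPOS],
    "TRANS_INTER_INV": [Category.DISTANCE, Category.CHRPOSORI, Category.CHRPOSORI],
}

#: expected read-depth state over the source region
EXPECTED_RD = {
    "DEL": "LOSS",
    "DUP_TANDEM": "GAIN",
    "GAIN_INTRA": "GAIN",
    "GAIN_INTRA_INV": "GAIN",
    "GAIN_INTER": "GAIN",
    "GAIN_INTER_INV": "GAIN",
    "INV": "NEUTRAL",
    "TRANS_INTRA": "NEUTRAL",
    "TRANS_INTRA_INV": "NEUTRAL",
    "TRANS_INTER": "NEUTRAL",
    "TRANS_INTER_INV": "NEUTRAL",
}


@dataclass(frozen=True)
class SvSpec:
    sv_class: str
    source_chrom: str
    source_start: int
    source_end: int
    insert_chrom: Optional[str] = None
    insert_pos: Optional[int] = None

    def __post_init__(self):
        if self.sv_class not in SV_CLASSES:
            raise ValueError(f"unknown SV class {self.sv_class!r}")
        if not self.source_start < self.source_end:
            raise ValueError("source_start must be < source_end")
        needs = self.sv_class in NEEDS_INSERT
        has = self.insert_chrom is not None and self.insert_pos is not None
        if needs and not has:
            raise ValueError(f"{self.sv_class} requires an insertion point")
        if not needs and (self.insert_chrom is not None or self.insert_pos is not None):
            raise ValueError(f"{self.sv_class} does not take an insertion point")

    @property
    def length(self) -> int:
        return self.source_end - self.source_start


@dataclass
class TruthRecord:
    spec: SvSpec
    junctions: list  # [(chrom, pos), ...] exact reference junction loci
    expected_categories: list
    expected_rd: str


@dataclass
class SimTruth:
    records: list = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


# ---------------------------------------------------------------------------
# reference


def simulate_reference(
    n_chroms: int,
    length: int,
    gc: Union[float, Callable[[float], float]] = 0.5,
    seed: int = 0,
) -> dict[str, str]:
    """Random reference; ``gc`` is a constant fraction or a callable of the
    fractional position along the chromosome (evaluated per 1 kb block, so
    per-kilobase GC tracks the profile up to binomial noise)."""
    if length <= 0:
        raise ValueError("chromosome length must be positive")
    if n_chroms <= 0:
        raise ValueError("need at least one chromosome")
    rng = np.random.default_rng(seed)
    chroms = {}
    block = 1000
    for c in range(n_chroms):
        name = f"chr{c + 1}"
        # exact GC count per 1 kb block (arrangement random): the emitted
        # per-kilobase GC then tracks the profile to rounding error
        is_gc = np.empty(length, dtype=bool)
        for b0 in range(0, length, block):
            blen = min(block, length - b0)
            centre = (b0 + blen / 2) / length
            frac = gc(centre) if callable(gc) else float(gc)
            frac = min(max(float(frac), 0.0), 1.0)
            n_gc = int(round(frac * blen))
            flags = np.zeros(blen, dtype=bool)
            flags[:n_gc] = True
            is_gc[b0 : b0 + blen] = rng.permutation(flags)
        which = rng.integers(0, 2, size=length)  # G/C or A/T choice
        codes = np.where(is_gc, np.where(which == 0, ord("G"), ord("C")),
                         np.where(which == 0, ord("A"), ord("T")))
        chroms[name] = codes.astype(np.uint8).tobytes().decode("ascii")
    return chroms


def gc_content(seq: str) -> float:
    s = seq.upper()
    return (s.count("G") + s.count("C")) / max(len(s), 1)


# ---------------------------------------------------------------------------
# donor construction

Block = tuple[str, int, int, str]  # (ref_chrom, ref_start, ref_end, strand)


@dataclass
class Donor:
    """A rearranged genome as per-chromosome lists of reference blocks."""

    blocks: dict[str, list[Block]]

    def lengths(self) -> dict[str, int]:
        return {c: sum(e - s for _, s, e, _ in bl) for c, bl in self.blocks.items()}

    def total_length(self) -> int:
        return sum(self.lengths().values())

    def sequence(self, reference: dict[str, str]) -> dict[str, str]:
        out = {}
        for chrom, bl in self.blocks.items():
            parts = []
            for rc, s, e, strand in bl:
                seg = reference[rc][s:e]
                parts.append(seg if strand == "+" else revcomp(seg))
            out[chrom] = "".join(parts)
        return out


_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _validate_specs(reference: dict[str, str], specs: Sequence[SvSpec]) -> None:
    regions: dict[str, list[tuple[int, int]]] = {}
    for sp in specs:
        if sp.source_chrom not in reference:
            raise ValueError(f"unknown chromosome {sp.source_chrom!r}")
        L = len(reference[sp.source_chrom])
        if not (0 <= sp.source_start < sp.source_end <= L):
            raise ValueError(f"source region out of bounds: {sp}")
        regions.setdefault(sp.source_chrom, []).append((sp.source_start, sp.source_end))
        if sp.insert_chrom is not None:
            if sp.insert_chrom not in reference:
                raise ValueError(f"unknown chromosome {sp.insert_chrom!r}")
            if not (0 <= sp.insert_pos <= len(reference[sp.insert_chrom])):
                raise ValueError(f"insertion point out of bounds: {sp}")
    for chrom, rs in regions.items():
        rs.sort()
        for (s1, e1), (s2, e2) in zip(rs, rs[1:]):
            if s2 < e1:
                raise ValueError(
                    f"overlapping source regions on {chrom}: [{s1},{e1}) and [{s2},{e2})"
                )
    # insertion points must not fall inside any source region
    for sp in specs:
        if sp.insert_chrom is None:
            continue
        for s, e in regions.get(sp.insert_chrom, []):
            if s < sp.insert_pos < e:
                raise ValueError(
                    f"insertion point {sp.insert_chrom}:{sp.insert_pos} lies "
                    f"inside a source region [{s},{e})"
                )


def apply_svs(reference: dict[str, str], specs: Sequence[SvSpec]) -> tuple[Donor, SimTruth]:
    """Apply non-overlapping SV specs to the reference, returning the donor
    block structure and the exact truth (junction loci, expected anomaly
    categories and expected depth state per variant)."""
    _validate_specs(reference, specs)

    # per-chromosome edits
    region_edits: dict[str, list[tuple[int, int, str]]] = {c: [] for c in reference}
    point_inserts: dict[str, list[tuple[int, int, list[Block]]]] = {c: [] for c in reference}
    truth = SimTruth()

    for idx, sp in enumerate(specs):
        c, s, e = sp.source_chrom, sp.source_start, sp.source_end
        cls = sp.sv_class
        junctions: list[tuple[str, int]] = []
        if cls == "DEL":
            region_edits[c].append((s, e, "del"))
            junctions = [(c, s), (c, e)]
        elif cls == "DUP_TANDEM":
            region_edits[c].append((s, e, "dup"))
            junctions = [(c, s), (c, e)]
        elif cls == "INV":
            region_edits[c].append((s, e, "inv"))
            junctions = [(c, s), (c, e)]
        elif cls.startswith("GAIN"):
            strand = "-" if cls.endswith("_INV") else "+"
            point_inserts[sp.insert_chrom].append((sp.insert_pos, idx, [(c, s, e, strand)]))
            junctions = [(c, s), (c, e), (sp.insert_chrom, sp.insert_pos)]
        elif cls.startswith("TRANS"):
            strand = "-" if cls.endswith("_INV") else "+"
            region_edits[c].append((s, e, "del"))
            point_inserts[sp.insert_chrom].append((sp.insert_pos, idx, [(c, s, e, strand)]))
            junctions = [(c, s), (c, e), (sp.insert_chrom, sp.insert_pos)]
        truth.records.append(
            TruthRecord(
                spec=sp,
                junctions=junctions,
                expected_categories=list(EXPECTED_CATEGORIES[cls]),
                expected_rd=EXPECTED_RD[cls],
            )
        )

    blocks: dict[str, list[Block]] = {}
    for chrom, seq in reference.items():
        L = len(seq)
        edits = sorted(region_edits[chrom])
        inserts = sorted(point_inserts[chrom])
        bl: list[Block] = []

        def emit(a: int, b: int) -> None:
            """Emit the plain reference stretch [a, b), interleaving any
            point insertions that fall inside it."""
            cur = a
            while inserts and inserts[0][0] <= b:
                p, _, ins_blocks = inserts.pop(0)
                if p < a:  # boundary shared with a region edit: insert first
                    p = a
                if cur < p:
                    bl.append((chrom, cur, p, "+"))
                bl.extend(ins_blocks)
                cur = p
            if cur < b:
                bl.append((chrom, cur, b, "+"))

        cursor = 0
        for s, e, kind in edits:
            emit(cursor, s)
            if kind == "del":
                pass
            elif kind == "dup":
                bl.append((chrom, s, e, "+"))
                bl.append((chrom, s, e, "+"))
            elif kind == "inv":
                bl.append((chrom, s, e, "-"))
            cursor = e
        emit(cursor, L)
        blocks[chrom] = bl
    return Donor(blocks), truth


# ---------------------------------------------------------------------------
# read pairs


def simulate_read_pairs(
    donor: Donor,
    read_len: int = 100,
    insert_mean: float = 300.0,
    insert_sd: float = 30.0,
    coverage: float = 30.0,
    seed: int = 0,
    phred: float = 40.0,
    mapq: int = 60,
    low_quality_fraction: float = 0.0,
    low_phred: float = 15.0,
    name_prefix: str = "rp",
) -> list[tuple[ReadAlignment, ReadAlignment]]:
    """Draw read pairs uniformly along the donor and map them back to
    reference coordinates through the block structure.

    The pair count per donor chromosome is ``coverage * len / (2 read_len)``.
    Reads falling entirely inside one block get exact reference coordinates
    (strand-flipped through inverted blocks); junction-spanning reads are
    emitted unmapped.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if insert_mean <= 2 * read_len:
        raise ValueError("insert_mean must exceed twice the read length")
    rng = np.random.default_rng(seed)
    pairs: list[tuple[ReadAlignment, ReadAlignment]] = []
    serial = 0
    for chrom in sorted(donor.blocks):
        bl = donor.blocks[chrom]
        dlen = sum(e - s for _, s, e, _ in bl)
        if dlen < insert_mean:
            continue
        n_pairs = int(round(coverage * dlen / (2 * read_len)))
        starts_off = np.concatenate(([0], np.cumsum([e - s for _, s, e, _ in bl])))
        inserts = rng.normal(insert_mean, insert_sd, size=n_pairs)
        inserts = np.maximum(np.rint(inserts).astype(np.int64), 2 * read_len)
        fstarts = rng.integers(0, np.maximum(dlen - inserts, 1))
        inserts = np.minimum(inserts, dlen - fstarts)
        lowq = (
            rng.random(n_pairs) < low_quality_fraction
            if low_quality_fraction > 0
            else np.zeros(n_pairs, dtype=bool)
        )

        def map_read(a: int, b: int) -> Optional[tuple[str, int, int, bool]]:
            """Map donor interval [a, b) -> (chrom, start, end, flip) or None."""
            i = int(np.searchsorted(starts_off, a, side="right")) - 1
            if b > starts_off[i + 1]:  # crosses a junction
                return None
            rc, rs, re, strand = bl[i]
            off_a, off_b = a - starts_off[i], b - starts_off[i]
            if strand == "+":
                return rc, rs + off_a, rs + off_b, False
            return rc, re - off_b, re - off_a, True

        for k in range(n_pairs):
            d1 = int(fstarts[k])
            ins = int(inserts[k])
            d2 = d1 + ins - read_len
            q = low_phred if lowq[k] else phred
            name = f"{name_prefix}_{chrom}_{serial:07d}"
            serial += 1
            m1 = map_read(d1, d1 + read_len)
            m2 = map_read(d2, d2 + read_len)
            r1 = _mk_read(name, m1, "+", q, mapq, True)
            r2 = _mk_read(name, m2, "-", q, mapq, False)
            pairs.append((r1, r2))
    return pairs


def _mk_read(name, mapping, donor_strand, baseq, mapq, read1) -> ReadAlignment:
    if mapping is None:
        return ReadAlignment(
            name=name, chrom=None, start=0, end=0, strand="+",
            mapq=0, baseq=baseq, mapped=False, read1=read1,
        )
    chrom, s, e, flip = mapping
    strand = donor_strand
    if flip:
        strand = "-" if strand == "+" else "+"
    return ReadAlignment(
        name=name, chrom=chrom, start=int(s), end=int(e), strand=strand,
        mapq=mapq, baseq=baseq, mapped=True, read1=read1,
    )


# ---------------------------------------------------------------------------
# convenience layouts


def default_sv_layout(chr1_len: int = 400_000, chr2_len: int = 250_000) -> list[SvSpec]:
    """One SV of every class, well separated on a two-chromosome genome."""
    return [
        SvSpec("DEL", "chr1", 20_000, 25_000),
        SvSpec("DUP_TANDEM", "chr1", 40_000, 42_000),
        SvSpec("INV", "chr1", 60_000, 63_000),
        SvSpec("GAIN_INTRA", "chr1", 80_000, 84_000, "chr1", 100_000),
        SvSpec("GAIN_INTRA_INV", "chr1", 120_000, 124_000, "chr1", 140_000),
        SvSpec("TRANS_INTRA", "chr1", 160_000, 164_000, "chr1", 185_000),
        SvSpec("TRANS_INTRA_INV", "chr1", 200_000, 204_000, "chr1", 225_000),
        SvSpec("GAIN_INTER", "chr1", 240_000, 244_000, "chr2", 50_000),
        SvSpec("GAIN_INTER_INV", "chr1", 260_000, 264_000, "chr2", 100_000),
        SvSpec("TRANS_INTER", "chr1", 280_000, 284_000, "chr2", 150_000),
        SvSpec("TRANS_INTER_INV", "chr1", 300_000, 304_000, "chr2", 200_000),
    ]


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_truth(truth: SimTruth, path) -> None:
    """Truth as a tab-separated table mirroring the call schema."""
    with open(path, "w") as fh:
        fh.write(
            "sv_class\tsource_chrom\tsource_start\tsource_end\t"
            "insert_chrom\tinsert_pos\texpected_rd\texpected_categories\n"
        )
        for rec in truth:
            sp = rec.spec
            fh.write(
                f"{sp.sv_class}\t{sp.source_chrom}\t{sp.source_start}\t{sp.source_end}\t"
                f"{sp.insert_chrom or '.'}\t{'.' if sp.insert_pos is None else sp.insert_pos}\t"
                f"{rec.expected_rd}\t{','.join(c.value for c in rec.expected_categories)}\n"
            )
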