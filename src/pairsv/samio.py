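"""SAM/BAM and FASTA plumbing around the in-memory record types."""

from __future__ import annotations

from typing import Iterable, Iterator, Optional

import pysam

from .classify import ReadAlignment, ReadPairRecord, triage_pair


def _mean_baseq(aln: pysam.AlignedSegment) -> float:
    q = aln.query_qualities
    if q is None or len(q) == 0:
        return 40.0
    return float(sum(q)) / len(q)


def _read_group(aln: pysam.AlignedSegment) -> Optional[str]:
    try:
        return aln.get_tag("RG")
    except KeyError:
        return None


def _to_alignment(aln: pysam.AlignedSegment) -> ReadAlignment:
    mapped = not aln.is_unmapped
    return ReadAlignment(
        name=aln.query_name,
        chrom=aln.reference_name if mapped else None,
        start=aln.reference_start if mapped else 0,
        end=aln.reference_end if mapped else 0,
        strand="-" if (mapped and aln.is_reverse) else "+",
        mapq=aln.mapping_quality,
        baseq=_mean_baseq(aln),
        mapped=mapped,
        read1=aln.is_read1 or not aln.is_read2,
        read_group=_read_group(aln),
    )


def iter_pairs(path: str) -> Iterator[ReadPairRecord]:
    """Stream triaged read pairs from a SAM/BAM file.

    Primary records only; mates are joined by name (the file need not keep
    mates adjacent).  Reads whose mate never appears are emitted as
    one-end-anchored pairs at the end.
    """
    pending: dict[str, ReadAlignment] = {}
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for aln in fh:
            if aln.is_secondary or aln.is_supplementary or not aln.is_paired:
                continue
            rec = _to_alignment(aln)
            mate = pending.pop(aln.query_name, None)
            if mate is None:
                pending[aln.query_name] = rec
            else:
                yield triage_pair(mate, rec)
    for name, rec in sorted(pending.items()):
        ghost = ReadAlignment(name=name, chrom=None, start=0, end=0, strand="+",
                              mapq=0, baseq=0.0, mapped=False, read1=not rec.read1)
        yield triage_pair(rec, ghost)


def write_sam(
    pairs: Iterable[tuple[ReadAlignment, ReadAlignment]],
    reference: dict[str, str],
    path: str,
    read_len: int = 100,
) -> None:
    """Write simulated pairs as a coordinate-sorted SAM file.

    Sequences are taken from the reference at the aligned position (the
    simulator emits error-free reads); unmapped reads get ``*``.  Base
    qualities are flat at each read's phred value.
    """
    chroms = sorted(reference)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(reference[c])} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}

    def make_segment(r: ReadAlignment, mate: ReadAlignment, first: bool) -> pysam.AlignedSegment:
        a = pysam.AlignedSegment()
        a.query_name = r.name
        a.flag = (
            0x1
            | (0x40 if first else 0x80)
            | (0x4 if not r.mapped else 0)
            | (0x8 if not mate.mapped else 0)
            | (0x10 if r.mapped and r.strand == "-" else 0)
            | (0x20 if mate.mapped and mate.strand == "-" else 0)
        )
        if r.mapped:
            a.reference_id = tid[r.chrom]
            a.reference_start = r.start
            a.mapping_quality = r.mapq
            a.cigarstring = f"{r.end - r.start}M"
            seq = reference[r.chrom][r.start:r.end]
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array(
                chr(int(round(r.baseq)) + 33) * len(seq)
            )
        elif mate.mapped:
            # convention: place the unmapped read at its mate's position
            a.reference_id = tid[mate.chrom]
            a.reference_start = mate.start
            a.mapping_quality = 0
            a.query_sequence = "N" * read_len
            a.query_qualities = pysam.qualitystring_to_array(
                chr(int(round(r.baseq)) + 33) * read_len
            )
        else:
            a.reference_id = -1
            a.reference_start = -1
            a.query_sequence = "N" * read_len
        if mate.mapped:
            a.next_reference_id = tid[mate.chrom]
            a.next_reference_start = mate.start
        else:
            a.next_reference_id = a.reference_id
            a.next_reference_start = a.reference_start
        return a

    rows = []
    for r1, r2 in pairs:
        rows.append(make_segment(r1, r2, True))
        rows.append(make_segment(r2, r1, False))
    rows.sort(key=lambda a: (a.reference_id if a.reference_id >= 0 else 1 << 30,
                             a.reference_start, a.query_name, a.flag))
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for a in rows:
            out.write(a)


def load_reference(path: str) -> dict[str, str]:
    """Load a FASTA into plain strings (toy-genome scale)."""
    try:
        from pyfaidx import Fasta
    except ImportError:  # pragma: no cover
        Fasta = None
    if Fasta is not None:
        with Fasta(path, as_raw=True, sequence_always_upper=True) as fa:
            return {name: str(fa[name][:]) for name in fa.keys()}
    out: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(parts)
                name = line[1:].split()[0]
                parts = []
            else:
                parts.append(line.upper())
    if name is not None:
        out[name] = "".join(parts)
    return out
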