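"""Repeat-aware filtering of unsupported calls.

Paired-read-only predictions whose breakpoints land in repetitive sequence
are the dominant source of false positives.  Calls that are *not* supported
by read depth or by a cluster combination (i.e. UNDEFINED and
PUTATIVE_DELETION calls) are therefore partitioned by a cascade over three
repeat classes -- a call is caught by the first track any of its predicted
breakpoint intervals intersects:

1. segmental duplications (SD),
2. simple sequence repeats (SSR),
3. low-divergence transposable elements (TE; > 90% identity to the family
   consensus, i.e. young enough to still mislead unique mapping).

Filtered calls are reported, not destroyed: repeats do mediate genuine
rearrangements, so the three bins stay available for inspection alongside
the passing set.  Passing calls are annotated with the identities of any
TEs overlapping their breakpoints.

Tracks are BED files (0-based half-open).  The TE track carries a value
column that is either a plain identity fraction (default) or a
RepeatMasker-style milli-divergence (``te_value="millidiv"``, identity =
1 - divergence/1000).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .interpret import SVCall

TE_IDENTITY_MIN = 0.9


@dataclass
class RepeatAnnotation:
    sd: dict[str, IntervalTree] = field(default_factory=dict)
    ssr: dict[str, IntervalTree] = field(default_factory=dict)
    te: dict[str, IntervalTree] = field(default_factory=dict)  # data = identity
    te_identity_min: float = TE_IDENTITY_MIN

    def _hits(self, trees: dict, chrom: str, lo: int, hi: int):
        tree = trees.get(chrom)
        if tree is None:
            return []
        return sorted(tree.overlap(lo, hi))

    def in_sd(self, chrom: str, lo: int, hi: int) -> bool:
        return bool(self._hits(self.sd, chrom, lo, hi))

    def in_ssr(self, chrom: str, lo: int, hi: int) -> bool:
        return bool(self._hits(self.ssr, chrom, lo, hi))

    def in_low_divergence_te(self, chrom: str, lo: int, hi: int) -> bool:
        return any(iv.data >= self.te_identity_min
                   for iv in self._hits(self.te, chrom, lo, hi))

    def te_identities(self, chrom: str, lo: int, hi: int) -> list[float]:
        return [iv.data for iv in self._hits(self.te, chrom, lo, hi)]


def _parse_bed(path, with_value: bool, value_kind: str) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                if end <= start:
                    raise ValueError("end <= start")
                if with_value:
                    raw = float(fields[4]) if len(fields) > 4 else float(fields[3])
                    value = 1.0 - raw / 1000.0 if value_kind == "millidiv" else raw
                    if not 0.0 <= value <= 1.0:
                        raise ValueError(f"identity {value} outside [0, 1]")
                else:
                    value = None
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed BED line {lineno}: {exc}") from exc
            trees.setdefault(chrom, IntervalTree()).addi(start, end, value)
    return trees


def load_tracks(
    sd_bed=None,
    ssr_bed=None,
    te_bed=None,
    te_value: str = "identity",
    te_identity_min: float = TE_IDENTITY_MIN,
) -> RepeatAnnotation:
    """Build the annotation from BED tracks (any of them optional; missing
    tracks filter nothing).  ``te_value`` selects the dialect of the TE value
    column: a plain identity fraction or RepeatMasker milli-divergence."""
    if te_value not in ("identity", "millidiv"):
        raise ValueError(f"unknown te_value dialect {te_value!r}")
    return RepeatAnnotation(
        sd=_parse_bed(sd_bed, False, te_value) if sd_bed else {},
        ssr=_parse_bed(ssr_bed, False, te_value) if ssr_bed else {},
        te=_parse_bed(te_bed, True, te_value) if te_bed else {},
        te_identity_min=te_identity_min,
    )


def partition_calls(
    calls: Sequence[SVCall],
    annotation: RepeatAnnotation,
) -> dict[str, list[SVCall]]:
    """Cascade partition {passed, in_sd, in_ssr, in_te}.

    Only filter-eligible calls (UNDEFINED / PUTATIVE_DELETION) are tested;
    depth- or combination-supported calls always pass, whatever their
    breakpoints overlap.  The cascade is exclusive: a call lands in the bin
    of the first track hit (SD before SSR before TE), testing every
    predicted breakpoint interval of the call.  Passing calls get their
    overlapping TE identities attached.
    """
    out: dict[str, list[SVCall]] = {"passed": [], "in_sd": [], "in_ssr": [], "in_te": []}
    for call in calls:
        bps = call.breakpoint_intervals
        if not bps and call.source_chrom is not None and call.source_interval:
            bps = [(call.source_chrom, *call.source_interval)]
        if call.defined:
            bucket = "passed"
        elif any(annotation.in_sd(c, lo, hi) for c, lo, hi in bps):
            bucket = "in_sd"
        elif any(annotation.in_ssr(c, lo, hi) for c, lo, hi in bps):
            bucket = "in_ssr"
        elif any(annotation.in_low_divergence_te(c, lo, hi) for c, lo, hi in bps):
            bucket = "in_te"
        else:
            bucket = "passed"
        if bucket == "passed":
            ids: list[float] = []
            for c, lo, hi in bps:
                ids.extend(annotation.te_identities(c, lo, hi))
            call.te_identities = sorted(set(ids))
        out[bucket].append(call)
    return out
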