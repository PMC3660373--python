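"""Repeat cascade on unsupported calls.

Depth- or combination-supported calls are immune; putative/undefined calls
are routed into the first repeat bin their breakpoints hit (segmental
duplication before simple repeat before young transposable element with
> 90% family identity).
"""

import tempfile
from pathlib import Path

from pairsv.interpret import SVCall
from pairsv.repeats import load_tracks, partition_calls

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    (tmp / "sd.bed").write_text("chr1\t1000\t2000\tSD_chr1_a\n")
    (tmp / "ssr.bed").write_text("chr1\t5000\t5100\t(AT)n\n")
    (tmp / "te.bed").write_text("chr1\t8000\t9000\tAluY\t0.95\n"
                                "chr1\t12000\t13000\tL1ME\t0.82\n")
    annotation = load_tracks(tmp / "sd.bed", tmp / "ssr.bed", tmp / "te.bed")

calls = [
    SVCall("UNDEFINED", source_chrom="chr1", source_interval=(1_500, 1_600)),
    SVCall("PUTATIVE_DELETION", source_chrom="chr1", source_interval=(5_020, 5_060)),
    SVCall("UNDEFINED", source_chrom="chr1", source_interval=(8_100, 8_300)),
    SVCall("UNDEFINED", source_chrom="chr1", source_interval=(12_100, 12_300)),
    SVCall("DELETION", source_chrom="chr1", source_interval=(1_400, 2_500)),
]

partition = partition_calls(calls, annotation)
for bucket, members in partition.items():
    print(f"{bucket:7s}: {len(members)} call(s)")
print("the defined DELETION passes despite sitting in the SD; the old TE "
      "(82% identity) does not catch its call; passed calls carry the "
      "identities of any TEs they touch:",
      [c.te_identities for c in partition["passed"]])
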