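"""End-to-end orchestration: SAM in, call files out.

The run produces a ``Results/`` tree with three sub-folders::

    Results/
      clusters/   per-category cluster tables (paired-read strategy)
      dofc/       per-window depth signal + per-segment state calls
      sv/         one call table per reported type, plus putative/undefined
                  and, when repeat tracks are given, the three filtered bins
      run_log.json

All randomness is seeded and all file ordering fixed by sort keys, so a
re-run with identical inputs and configuration is byte-identical; with
``workers > 1`` the per-chromosome-group stages run in a process pool and
are merged back in sorted order, so parallel output equals serial output.
"""

from __future__ import annotations

import json
import os
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .classify import ANOMALOUS, Category, ReadPairRecord, classify_pairs
from .cluster import (
    Cluster,
    annotate_confidence,
    assign_ids,
    cluster_anomalous,
    predict_breakpoints,
)
from .depth import (
    DEFAULT_WINDOW,
    GAIN_THRESHOLD,
    LOSS_THRESHOLD,
    MIN_BIN_WINDOWS,
    DepthSegment,
    bin_reads,
    gc_normalize,
    segment_windows,
    transform,
)
from .insert_size import DEFAULT_ALPHA, ModelSet, estimate_from_pairs
from .interpret import SVCall, define_svs, subtract_shared
from .repeats import load_tracks, partition_calls
from .samio import iter_pairs, load_reference
from .segment import DEFAULT_T


@dataclass
class RunConfig:
    tumour: str  # SAM/BAM path of the (primary) sample
    reference: str  # FASTA path
    normal: Optional[str] = None
    sd_bed: Optional[str] = None
    ssr_bed: Optional[str] = None
    te_bed: Optional[str] = None
    te_value: str = "identity"
    alpha: float = DEFAULT_ALPHA
    window_size: int = DEFAULT_WINDOW
    gain_threshold: float = GAIN_THRESHOLD
    loss_threshold: float = LOSS_THRESHOLD
    segment_t: float = DEFAULT_T
    min_bin_windows: int = MIN_BIN_WINDOWS
    min_support: int = 2
    mapq_floor: int = 1
    q_tiers: tuple = (30.0, 20.0)
    breakpoint_tolerance: int = 0
    library_type: str = "paired_end"
    somatic: bool = False
    seed: int = 0
    workers: int = 1
    cluster_distance: Optional[float] = None  # default UC - LC

    def validate(self) -> None:
        if self.somatic and not self.normal:
            raise ValueError("somatic mode requires a matched normal sample")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if self.library_type not in ("paired_end", "mate_pair"):
            raise ValueError(f"unknown library_type {self.library_type!r}")


@dataclass
class SampleData:
    models: ModelSet
    anomalous: list  # classified anomalous ReadPairRecords
    depth_reads: list  # (chrom, start, end) of every mapped read
    counts: dict


@dataclass
class RunResult:
    config: RunConfig
    clusters: list
    segments: list
    windows: object  # per-window DataFrame
    calls: list
    partition: Optional[dict]
    counts: dict


def load_sample(path: str, config: RunConfig) -> SampleData:
    """Read, triage and classify one sample; collect depth reads."""
    pairs = list(iter_pairs(path))
    models = estimate_from_pairs((p for p in pairs), alpha=config.alpha)
    counts = {c.value: 0 for c in Category}
    counts["total_pairs"] = len(pairs)
    anomalous = []
    depth_reads = []
    for rp in classify_pairs(pairs, models, config.library_type, config.mapq_floor):
        counts[rp.category.value] += 1
        for read in (rp.read_a, rp.read_b):
            if read.mapped:
                depth_reads.append((read.chrom, read.start, read.end))
        if rp.category in ANOMALOUS:
            anomalous.append(rp)
    counts["mapq_filtered"] = counts["total_pairs"] - sum(
        counts[c.value] for c in Category
    )
    return SampleData(models=models, anomalous=anomalous,
                      depth_reads=depth_reads, counts=counts)


def mean_coverage(depth_reads: Sequence, reference: dict) -> float:
    total_bases = sum(e - s for _, s, e in depth_reads)
    genome = sum(len(s) for s in reference.values())
    return total_bases / genome if genome else 0.0


def _segment_chrom(args):
    windows, t, gain, loss = args
    return segment_windows(windows, t_threshold=t, gain=gain, loss=loss)


def run(config: RunConfig, outdir: str) -> RunResult:
    """Execute the full workflow and write the results tree."""
    config.validate()
    reference = load_reference(config.reference)

    tumour = load_sample(config.tumour, config)
    model = tumour.models.default
    D = config.cluster_distance if config.cluster_distance is not None else model.D

    chrom_lengths = {c: len(s) for c, s in reference.items()}
    clusters = cluster_anomalous(tumour.anomalous, model, D=D,
                                 min_support=config.min_support)
    cov = mean_coverage(tumour.depth_reads, reference)
    for cl in clusters:
        predict_breakpoints(cl, tumour.models.for_pair(cl.members[0]), chrom_lengths)
        annotate_confidence(cl, cov, config.q_tiers)
    assign_ids(clusters)

    counts = {"tumour": tumour.counts, "mean_coverage": cov}

    if config.somatic:
        normal = load_sample(config.normal, config)
        counts["normal"] = normal.counts
        clusters = subtract_shared(clusters, normal.anomalous, model, D=D)
        counts["somatic_clusters"] = len(clusters)

    windows = bin_reads(tumour.depth_reads, config.window_size, reference)
    windows = gc_normalize(windows, min_bin_windows=config.min_bin_windows)
    windows = transform(windows)
    segments = _segment_all(windows, config)

    calls = define_svs(
        clusters,
        segments,
        window_size=config.window_size,
        tolerance=config.breakpoint_tolerance,
    )
    if config.somatic:
        for call in calls:
            call.somatic = True

    partition = None
    if config.sd_bed or config.ssr_bed or config.te_bed:
        annotation = load_tracks(config.sd_bed, config.ssr_bed, config.te_bed,
                                 te_value=config.te_value)
        partition = partition_calls(calls, annotation)

    counts["clusters"] = len(clusters)
    counts["calls"] = {t: sum(1 for c in calls if c.reported_type == t)
                       for t in sorted({c.reported_type for c in calls})}
    _write_results(outdir, config, clusters, windows, segments, calls, partition, counts)
    return RunResult(config=config, clusters=clusters, segments=segments,
                     windows=windows, calls=calls, partition=partition, counts=counts)


def _segment_all(windows, config: RunConfig) -> list:
    chroms = sorted(windows["chrom"].unique())
    jobs = [
        (windows[windows["chrom"] == c], config.segment_t,
         config.gain_threshold, config.loss_threshold)
        for c in chroms
    ]
    if config.workers > 1 and len(jobs) > 1:
        with ProcessPoolExecutor(max_workers=config.workers) as pool:
            parts = list(pool.map(_segment_chrom, jobs))
    else:
        parts = [_segment_chrom(j) for j in jobs]
    segments: list = []
    for part in parts:
        segments.extend(part)
    segments.sort(key=lambda s: (s.chrom, s.start))
    return segments


# ---------------------------------------------------------------------------
# output writing (1-based inclusive coordinates in user-facing tables)


def _fmt_interval(iv) -> str:
    if iv is None:
        return ".\t."
    return f"{iv[0] + 1}\t{iv[1]}"


def _write_clusters(folder: str, clusters: Sequence[Cluster]) -> None:
    os.makedirs(folder, exist_ok=True)
    by_cat: dict = {}
    for c in clusters:
        by_cat.setdefault(c.category.value.lower(), []).append(c)
    header = (
        "cluster_id\tcategory\tchromA\tbpA_start\tbpA_end\tchromB\tbpB_start\tbpB_end\t"
        "S\tstrandA\tstrandB\tq_tier\tsupport_tier\tlength_tier\tunreliable\tread_names\n"
    )
    for cat, cs in sorted(by_cat.items()):
        with open(os.path.join(folder, f"{cat}_clusters.tsv"), "w") as fh:
            fh.write(header)
            for c in cs:
                names = ",".join(sorted(m.name for m in c.members))
                fh.write(
                    f"{c.cluster_id}\t{c.category.value}\t{c.chromA}\t{_fmt_interval(c.bpA)}\t"
                    f"{c.chromB}\t{_fmt_interval(c.bpB)}\t{c.S}\t{c.sideA.strand}\t"
                    f"{c.sideB.strand}\t{c.q_tier}\t{c.support_tier}\t{c.length_tier}\t"
                    f"{int(c.unreliable)}\t{names}\n"
                )


def _write_depth(folder: str, windows, segments: Sequence[DepthSegment]) -> None:
    os.makedirs(folder, exist_ok=True)
    cols = windows.loc[~windows["masked"], ["chrom", "start", "end", "y"]]
    with open(os.path.join(folder, "signal.bedgraph"), "w") as fh:
        for row in cols.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.y:.4f}\n")
    with open(os.path.join(folder, "segments.bed"), "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.state}\t{s.mean_y:.4f}\n")


def _call_row(call: SVCall) -> str:
    return (
        f"{call.sv_class}\t{call.reported_type}\t{call.source_chrom}\t"
        f"{_fmt_interval(call.source_interval)}\t"
        f"{call.insertion_chrom or '.'}\t{_fmt_interval(call.insertion_interval)}\t"
        f"{call.orientation or '.'}\t{call.rd_state or '.'}\t{call.support}\t"
        f"{';'.join(call.cluster_ids)}\t"
        f"{'somatic' if call.somatic else '.' if call.somatic is None else 'germline'}\t"
        f"{';'.join(call.flags) or '.'}\t"
        f"{';'.join(f'{x:.3f}' for x in call.te_identities) or '.'}\n"
    )


_CALL_HEADER = (
    "sv_class\treported_type\tsource_chrom\tsource_start\tsource_end\t"
    "insert_chrom\tinsert_start\tinsert_end\torientation\trd_state\tsupport\t"
    "clusters\tsomatic\tflags\tte_identities\n"
)


def _write_calls(folder: str, calls: Sequence[SVCall],
                 partition: Optional[dict]) -> None:
    os.makedirs(folder, exist_ok=True)
    groups: dict[str, list] = {}
    for call in calls:
        groups.setdefault(call.reported_type, []).append(call)
    for name, cs in sorted(groups.items()):
        cs.sort(key=lambda c: (c.source_chrom or "", c.source_interval or (0, 0)))
        with open(os.path.join(folder, f"{name}.tsv"), "w") as fh:
            fh.write(_CALL_HEADER)
            for call in cs:
                fh.write(_call_row(call))
    if partition is not None:
        for bucket, cs in partition.items():
            path = os.path.join(folder, f"filter_{bucket}.tsv")
            with open(path, "w") as fh:
                fh.write(_CALL_HEADER)
                for call in sorted(
                    cs, key=lambda c: (c.source_chrom or "", c.source_interval or (0, 0))
                ):
                    fh.write(_call_row(call))


def _write_results(outdir, config, clusters, windows, segments, calls,
                   partition, counts) -> None:
    results = os.path.join(outdir, "Results")
    os.makedirs(results, exist_ok=True)
    _write_clusters(os.path.join(results, "clusters"), clusters)
    _write_depth(os.path.join(results, "dofc"), windows, segments)
    _write_calls(os.path.join(results, "sv"), calls, partition)
    log = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "counts": counts,
    }
    with open(os.path.join(results, "run_log.json"), "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
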