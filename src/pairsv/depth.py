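"""GC-normalised read-depth signal and gain/loss segmentation.

Each chromosome is tiled with fixed windows; every mapped read (one- or
two-end anchored alike) increments the single window holding the largest
share of its bases.  Counts are corrected for GC composition by the
median-ratio adjustment ``r_adj = r * m / m_GC``, where ``m`` is the global
median count and ``m_GC`` the median over windows sharing the window's GC
percentage; the corrected signal is variance-stabilised with a square root
and centred on the global median, ``y = sqrt(r_adj) - sqrt(median(r_adj))``,
so that copy-neutral windows sit near 0.  Piecewise-constant segmentation
of ``y`` (see :mod:`pairsv.segment`) then yields segments whose mean above
+0.4 / below -0.4 is called GAIN / LOSS (thresholds configurable).

Windows dominated by N bases (> 50%) and GC bins too sparse for a stable
median are masked and excluded from normalisation and segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .segment import DEFAULT_T, segment_signal

DEFAULT_WINDOW = 100
GAIN_THRESHOLD = 0.4
LOSS_THRESHOLD = -0.4
#: a GC bin needs at least this many windows for a stable median
MIN_BIN_WINDOWS = 50
MAX_N_FRACTION = 0.5


@dataclass
class DepthSegment:
    chrom: str
    start: int
    end: int
    mean_y: float
    state: str  # 'GAIN' | 'LOSS' | 'NEUTRAL'
    n_windows: int = 0


def call_state(mean_y: float, gain: float = GAIN_THRESHOLD,
               loss: float = LOSS_THRESHOLD) -> str:
    if mean_y > gain:
        return "GAIN"
    if mean_y < loss:
        return "LOSS"
    return "NEUTRAL"


def _window_gc(seq: str, window_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-window GC percentage (over non-N bases) and N fraction."""
    b = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    is_gc = (b == ord("G")) | (b == ord("C"))
    is_n = ~((b == ord("A")) | (b == ord("T")) | is_gc)
    n_win = (len(b) + window_size - 1) // window_size
    pad = n_win * window_size - len(b)
    if pad:
        is_gc = np.pad(is_gc, (0, pad))
        is_n = np.pad(is_n, (0, pad), constant_values=True)
    gc_w = is_gc.reshape(n_win, window_size).sum(axis=1)
    n_w = is_n.reshape(n_win, window_size).sum(axis=1)
    sizes = np.full(n_win, window_size)
    sizes[-1] = window_size - pad
    denom = np.maximum(sizes - n_w, 1)
    gc_pct = np.rint(100.0 * gc_w / denom).astype(int)
    return gc_pct, n_w / sizes


def _assign_windows(starts: np.ndarray, ends: np.ndarray, w: int) -> np.ndarray:
    """Majority-overlap window index per read; 50/50 ties go left."""
    wa = starts // w
    wb = (ends - 1) // w
    left_overlap = (wa + 1) * w - starts
    right_overlap = ends - wb * w
    # a read spanning >2 windows fully covers wa+1; leftmost maximal overlap
    spans_middle = wb > wa + 1
    choose = np.where(
        wa == wb,
        wa,
        np.where(
            spans_middle,
            np.where(left_overlap >= w, wa, wa + 1),
            np.where(left_overlap >= right_overlap, wa, wb),
        ),
    )
    return choose


def bin_reads(
    reads: Iterable[tuple[str, int, int]],
    window_size: int,
    reference,
) -> pd.DataFrame:
    """Count reads per fixed window and annotate window GC.

    ``reads`` yields ``(chrom, start, end)`` for every mapped read;
    ``reference`` maps chromosome name to sequence (dict of str or a
    ``pyfaidx.Fasta``).  Returns one row per window with columns
    ``chrom, start, end, r, gc_bin, masked`` (masked = N-dense window).
    """
    by_chrom: dict[str, list] = {}
    for chrom, s, e in reads:
        by_chrom.setdefault(chrom, []).append((s, e))
    frames = []
    for chrom in sorted(_ref_chroms(reference)):
        seq = _ref_seq(reference, chrom)
        L = len(seq)
        n_win = (L + window_size - 1) // window_size
        gc_pct, n_frac = _window_gc(seq, window_size)
        r = np.zeros(n_win, dtype=np.int64)
        items = by_chrom.get(chrom)
        if items:
            arr = np.asarray(items, dtype=np.int64)
            idx = _assign_windows(arr[:, 0], arr[:, 1], window_size)
            idx = np.clip(idx, 0, n_win - 1)
            np.add.at(r, idx, 1)
        starts = np.arange(n_win, dtype=np.int64) * window_size
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": np.minimum(starts + window_size, L),
                    "r": r,
                    "gc_bin": gc_pct,
                    "masked": n_frac > MAX_N_FRACTION,
                }
            )
        )
    if not frames:
        raise ValueError("reference has no sequences")
    return pd.concat(frames, ignore_index=True)


def _ref_chroms(reference) -> list[str]:
    return list(reference.keys())


def _ref_seq(reference, chrom: str) -> str:
    s = reference[chrom]
    return s if isinstance(s, str) else str(s[:])


def gc_normalize(windows: pd.DataFrame, min_bin_windows: int = MIN_BIN_WINDOWS) -> pd.DataFrame:
    """Median-ratio GC correction: ``r_adj = r * m / m_GC``.

    GC bins occupied by fewer than ``min_bin_windows`` windows, or whose
    median count is zero, are masked (their windows drop out of the
    segmentation).  Raises if every unmasked window has zero count.
    """
    df = windows.copy()
    ok = ~df["masked"]
    if not ok.any() or df.loc[ok, "r"].sum() == 0:
        raise ValueError("no usable read-depth signal (all windows empty or masked)")
    m = float(df.loc[ok, "r"].median())
    stats = df.loc[ok].groupby("gc_bin")["r"].agg(["median", "size"])
    m_gc = df["gc_bin"].map(stats["median"])
    bin_n = df["gc_bin"].map(stats["size"]).fillna(0)
    bad = ok & ((bin_n < min_bin_windows) | (m_gc <= 0) | m_gc.isna())
    df.loc[bad, "masked"] = True
    ok = ~df["masked"]
    df["r_adj"] = np.nan
    df.loc[ok, "r_adj"] = df.loc[ok, "r"] * m / m_gc[ok]
    return df


def transform(windows: pd.DataFrame) -> pd.DataFrame:
    """Square-root transform shifted to centre copy-neutral windows at 0."""
    df = windows.copy()
    ok = ~df["masked"]
    med = float(df.loc[ok, "r_adj"].median())
    df["y"] = np.nan
    df.loc[ok, "y"] = np.sqrt(df.loc[ok, "r_adj"]) - np.sqrt(med)
    return df


def segment_windows(
    windows: pd.DataFrame,
    t_threshold: float = DEFAULT_T,
    gain: float = GAIN_THRESHOLD,
    loss: float = LOSS_THRESHOLD,
) -> list[DepthSegment]:
    """Segment the transformed signal chromosome by chromosome.

    Masked windows are removed first; the unmasked windows of each
    chromosome form one sequence whose segments tile it without overlap.
    Segment boundaries are reported in base-pair coordinates of the first
    and last window of each segment.
    """
    out: list[DepthSegment] = []
    for chrom, sub in windows[~windows["masked"]].groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        y = sub["y"].to_numpy()
        if len(y) == 0:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        for s, e, mean in segment_signal(y, t_threshold=t_threshold):
            out.append(
                DepthSegment(
                    chrom=str(chrom),
                    start=int(starts[s]),
                    end=int(ends[e - 1]),
                    mean_y=float(mean),
                    state=call_state(mean, gain, loss),
                    n_windows=int(e - s),
                )
            )
    return out


def depth_pipeline(
    reads: Iterable[tuple[str, int, int]],
    reference,
    window_size: int = DEFAULT_WINDOW,
    min_bin_windows: int = MIN_BIN_WINDOWS,
    t_threshold: float = DEFAULT_T,
    gain: float = GAIN_THRESHOLD,
    loss: float = LOSS_THRESHOLD,
) -> tuple[pd.DataFrame, list[DepthSegment]]:
    """bin -> GC-normalise -> transform -> segment, returning both the
    per-window table and the segment calls."""
    win = bin_reads(reads, window_size, reference)
    win = gc_normalize(win, min_bin_windows=min_bin_windows)
    win = transform(win)
    segs = segment_windows(win, t_threshold=t_threshold, gain=gain, loss=loss)
    return win, segs
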