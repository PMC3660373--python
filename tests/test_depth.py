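"""Read depth: binning, GC correction, transform and segmentation."""

import numpy as np
import pandas as pd
import pytest

from pairsv.depth import (
    DepthSegment,
    bin_reads,
    call_state,
    depth_pipeline,
    gc_normalize,
    segment_windows,
    transform,
)
from pairsv.segment import changepoints, segment_signal


class TestSegmentSignal:
    def test_constant_signal_is_one_segment(self):
        segs = segment_signal(np.zeros(10_000))
        assert segs == [(0, 10_000, 0.0)]

    def test_noise_free_steps_kept_exactly(self):
        y = np.concatenate([np.zeros(50), np.full(30, 2.0), np.zeros(40)])
        segs = segment_signal(y)
        assert changepoints(segs) == [50, 80]

    @pytest.mark.parametrize("seed", range(6))
    def test_step_recovery_within_two_windows(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(0, 0.3, 4_000)
        y[2_000:2_050] -= 1.5  # SNR = 5
        segs = segment_signal(y, 5.0)
        cps = changepoints(segs)
        assert any(abs(c - 2_000) <= 2 for c in cps)
        assert any(abs(c - 2_050) <= 2 for c in cps)
        assert len(cps) <= 4

    def test_adjacent_opposite_steps_not_merged(self):
        rng = np.random.default_rng(3)
        y = rng.normal(0, 0.2, 2_000)
        y[900:950] += 1.5
        y[950:1_000] -= 1.5
        segs = segment_signal(y, 5.0)
        means = [m for _, _, m in segs]
        assert any(m > 1.0 for m in means) and any(m < -1.0 for m in means)

    def test_segments_tile_the_signal(self):
        rng = np.random.default_rng(8)
        y = rng.normal(0, 1, 500)
        segs = segment_signal(y, 4.0)
        assert segs[0][0] == 0 and segs[-1][1] == 500
        for (s1, e1, _), (s2, e2, _) in zip(segs, segs[1:]):
            assert e1 == s2


class TestBinning:
    REF = {"chr1": "ACGT" * 250}  # 1 kb, GC 50%

    def test_majority_window_assignment(self):
        # read covering 60 bp of window 0 and 40 bp of window 1
        win = bin_reads([("chr1", 40, 140)], 100, self.REF)
        assert win.loc[0, "r"] == 1 and win.loc[1, "r"] == 0

    def test_fifty_fifty_tie_goes_left(self):
        win = bin_reads([("chr1", 50, 150)], 100, self.REF)
        assert win.loc[0, "r"] == 1 and win.loc[1, "r"] == 0

    def test_long_read_takes_leftmost_full_window(self):
        win = bin_reads([("chr1", 80, 380)], 100, self.REF)
        assert win.loc[1, "r"] == 1

    def test_count_conservation(self):
        rng = np.random.default_rng(4)
        starts = rng.integers(0, 900, 500)
        reads = [("chr1", int(s), int(s) + 100) for s in starts]
        win = bin_reads(reads, 100, self.REF)
        assert win["r"].sum() == 500

    def test_n_dense_windows_masked(self):
        ref = {"chr1": "A" * 100 + "N" * 100 + "G" * 100}
        win = bin_reads([], 100, ref)
        assert list(win["masked"]) == [False, True, False]
        assert list(win["gc_bin"]) == [0, 0, 100]


def _flat_windows(n=600, r=30, gc=50):
    return pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(n) * 100,
        "end": (np.arange(n) + 1) * 100,
        "r": np.full(n, r),
        "gc_bin": np.full(n, gc),
        "masked": False,
    })


class TestGcNormalize:
    def test_identity_on_single_bin(self):
        win = gc_normalize(_flat_windows())
        assert np.allclose(win["r_adj"], win["r"])

    def test_idempotent_on_flat_signal(self):
        win = gc_normalize(_flat_windows())
        again = gc_normalize(win.assign(r=win["r_adj"].round().astype(int)))
        assert np.allclose(again["r_adj"], win["r_adj"])

    def test_engineered_gc_bias_flattened(self):
        rng = np.random.default_rng(5)
        n = 4_000
        gc_bin = rng.integers(35, 56, n)
        base = rng.poisson(30, n)
        # high-GC windows get double depth
        r = np.where(gc_bin >= 45, base * 2, base)
        win = pd.DataFrame({
            "chrom": "chr1", "start": np.arange(n) * 100,
            "end": (np.arange(n) + 1) * 100, "r": r,
            "gc_bin": gc_bin, "masked": False,
        })
        out = gc_normalize(win)
        med = out.loc[~out["masked"]].groupby("gc_bin")["r_adj"].median()
        global_med = out.loc[~out["masked"], "r_adj"].median()
        assert (abs(med - global_med) / global_med).max() <= 0.05

    def test_zero_count_window_stays_zero(self):
        win = _flat_windows()
        win.loc[10, "r"] = 0
        out = gc_normalize(win)
        assert out.loc[10, "r_adj"] == 0

    def test_sparse_gc_bins_are_masked(self):
        win = _flat_windows(600)
        win.loc[:4, "gc_bin"] = 99  # only 5 windows in this bin
        out = gc_normalize(win, min_bin_windows=50)
        assert out.loc[:4, "masked"].all()

    def test_all_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            gc_normalize(_flat_windows(r=0))


class TestTransform:
    def test_median_window_maps_to_zero(self):
        win = transform(gc_normalize(_flat_windows()))
        assert np.allclose(win["y"], 0.0)

    def test_homozygous_loss_amplitude(self):
        win = _flat_windows(n=600, r=36)
        win.loc[100:149, "r"] = 0
        out = transform(gc_normalize(win))
        assert out.loc[100, "y"] == pytest.approx(-6.0)

    def test_state_calling_monotone(self):
        ys = [-1.0, -0.41, -0.4, 0.0, 0.4, 0.41, 1.0]
        states = [call_state(y) for y in ys]
        assert states == ["LOSS", "LOSS", "NEUTRAL", "NEUTRAL", "NEUTRAL",
                          "GAIN", "GAIN"]


class TestSegmentWindows:
    def test_constant_signal_single_neutral_segment(self):
        win = transform(gc_normalize(_flat_windows(2_000)))
        segs = segment_windows(win)
        assert len(segs) == 1
        assert segs[0].state == "NEUTRAL"
        assert (segs[0].start, segs[0].end) == (0, 200_000)

    def test_single_copy_loss_and_gain_cross_thresholds(self):
        """Diploid 30x: one lost copy -> 15x, one gained copy -> 45x; the
        segment means must cross the -0.4 / +0.4 state thresholds."""
        rng = np.random.default_rng(17)
        n = 3_000
        r = rng.poisson(30, n)
        r[500:600] = rng.poisson(15, 100)   # heterozygous loss
        r[1_500:1_600] = rng.poisson(45, 100)  # single-copy gain
        win = _flat_windows(n)
        win["r"] = r
        segs = segment_windows(transform(gc_normalize(win)))
        loss = [s for s in segs if s.state == "LOSS"]
        gain = [s for s in segs if s.state == "GAIN"]
        assert any(abs(s.start - 50_000) <= 200 and s.mean_y < -0.4 for s in loss)
        assert any(abs(s.start - 150_000) <= 200 and s.mean_y > 0.4 for s in gain)

    def test_segments_tile_each_chromosome(self, eleven_class_run):
        segs = eleven_class_run["segments"]
        by_chrom = {}
        for s in segs:
            by_chrom.setdefault(s.chrom, []).append(s)
        for chrom, ss in by_chrom.items():
            ss.sort(key=lambda s: s.start)
            for a, b in zip(ss, ss[1:]):
                assert a.end <= b.start  # no overlap (masked gaps allowed)


class TestEndToEndDepth:
    def test_uniform_coverage_count_oracle(self):
        from pairsv.simulate import apply_svs, simulate_read_pairs, simulate_reference

        ref = simulate_reference(1, 50_000, seed=41)
        donor, _ = apply_svs(ref, [])
        reads = [(r.chrom, r.start, r.end)
                 for p in simulate_read_pairs(donor, coverage=30, seed=42)
                 for r in p if r.mapped]
        win = bin_reads(reads, 100, ref)
        assert win["r"].sum() == len(reads)  # conservation through binning
        # direct count: reads per window = 2 * pairs * read_len / genome
        assert win["r"].mean() == pytest.approx(len(reads) / len(win), rel=1e-6)
        assert abs(win["r"].mean() - 30.0) < 1.0
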