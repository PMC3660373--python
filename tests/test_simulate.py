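"""Generator correctness: GC control, donor bookkeeping, pair geometry."""

import numpy as np
import pytest

from pairsv import classify, insert_size, simulate
from pairsv.simulate import SvSpec, apply_svs, simulate_read_pairs, simulate_reference


class TestReference:
    def test_gc_tracks_constant_profile(self):
        ref = simulate_reference(1, 100_000, gc=0.5, seed=7)
        assert 0.48 <= simulate.gc_content(ref["chr1"]) <= 0.52

    def test_degenerate_profile_yields_at_only(self):
        ref = simulate_reference(1, 1_000, gc=0.0, seed=1)
        assert set(ref["chr1"]) <= {"A", "T"}

    def test_deterministic_under_seed(self):
        a = simulate_reference(2, 20_000, gc=0.4, seed=42)
        b = simulate_reference(2, 20_000, gc=0.4, seed=42)
        assert a == b

    def test_positional_profile_tracked_per_kilobase(self):
        ref = simulate_reference(1, 50_000, gc=lambda x: 0.3 + 0.4 * x, seed=3)
        seq = ref["chr1"]
        for k in range(0, 50):
            want = 0.3 + 0.4 * (k * 1000 + 500) / 50_000
            got = simulate.gc_content(seq[k * 1000 : (k + 1) * 1000])
            assert abs(got - want) <= 0.05

    def test_rejects_bad_sizes(self):
        with pytest.raises(ValueError):
            simulate_reference(1, 0, seed=1)
        with pytest.raises(ValueError):
            simulate_reference(0, 1000, seed=1)


@pytest.fixture(scope="module")
def ref_two():
    return simulate_reference(2, 100_000, gc=0.5, seed=9)


@pytest.fixture(scope="module")
def ref_one():
    return simulate_reference(1, 100_000, gc=0.5, seed=13)


class TestApplySvs:

    def test_deletion_shortens_donor(self, ref_two):
        donor, _ = apply_svs(ref_two, [SvSpec("DEL", "chr1", 40_000, 45_000)])
        assert donor.lengths()["chr1"] == 95_000

    def test_tandem_duplication_lengthens_donor(self, ref_two):
        donor, _ = apply_svs(ref_two, [SvSpec("DUP_TANDEM", "chr1", 10_000, 12_000)])
        assert donor.lengths()["chr1"] == 102_000

    def test_inversion_preserves_length_and_reverse_complements(self, ref_two):
        donor, _ = apply_svs(ref_two, [SvSpec("INV", "chr1", 30_000, 33_000)])
        assert donor.lengths()["chr1"] == 100_000
        seq = donor.sequence(ref_two)["chr1"]
        assert seq[30_000:33_000] == simulate.revcomp(ref_two["chr1"][30_000:33_000])
        assert seq[:30_000] == ref_two["chr1"][:30_000]

    def test_length_bookkeeping_across_all_classes(self, ref_two):
        specs = [
            SvSpec("DEL", "chr1", 5_000, 8_000),
            SvSpec("DUP_TANDEM", "chr1", 20_000, 21_000),
            SvSpec("GAIN_INTER", "chr1", 40_000, 44_000, "chr2", 50_000),
            SvSpec("TRANS_INTER", "chr1", 60_000, 62_000, "chr2", 70_000),
            SvSpec("INV", "chr2", 10_000, 12_000),
        ]
        donor, truth = apply_svs(ref_two, specs)
        # -3000 (del) +1000 (dup) +4000 (copy) +0 (cut-paste) +0 (inv)
        assert donor.total_length() == 200_000 - 3_000 + 1_000 + 4_000
        assert len(truth) == len(specs)
        for rec in truth:
            assert len(rec.junctions) >= 2

    def test_overlapping_sources_rejected(self, ref_two):
        with pytest.raises(ValueError, match="overlap"):
            apply_svs(ref_two, [SvSpec("DEL", "chr1", 10_000, 20_000),
                            SvSpec("INV", "chr1", 15_000, 25_000)])

    def test_insertion_inside_source_rejected(self, ref_two):
        with pytest.raises(ValueError, match="inside"):
            apply_svs(ref_two, [SvSpec("TRANS_INTRA", "chr1", 10_000, 20_000,
                                   "chr1", 15_000)])

    def test_spec_invariants(self):
        with pytest.raises(ValueError):
            SvSpec("DEL", "chr1", 100, 100)
        with pytest.raises(ValueError):
            SvSpec("GAIN_INTRA", "chr1", 100, 200)  # insertion point missing
        with pytest.raises(ValueError):
            SvSpec("DEL", "chr1", 100, 200, "chr1", 500)  # spurious insertion


class TestReadPairs:

    def test_sv_free_library_is_almost_all_concordant(self, ref_one):
        donor, _ = apply_svs(ref_one, [])
        raw = simulate_read_pairs(donor, insert_mean=300, insert_sd=30,
                                  coverage=20, seed=21)
        pairs = [classify.triage_pair(a, b) for a, b in raw]
        models = insert_size.estimate_from_pairs(pairs, alpha=0.01)
        cats = [classify.classify_pair(p, models.default) for p in pairs
                if p.category is None]
        frac = sum(c is classify.Category.CONCORDANT for c in cats) / len(cats)
        assert frac >= 0.99 - 3 * np.sqrt(0.01 * 0.99 / len(cats))

    def test_deletion_spanning_pairs_show_stretched_gap(self, ref_one):
        d = 5_000
        donor, _ = apply_svs(ref_one, [SvSpec("DEL", "chr1", 40_000, 40_000 + d)])
        raw = simulate_read_pairs(donor, insert_mean=300, insert_sd=30,
                                  coverage=30, seed=22)
        spanning = [
            b.start - a.end
            for a, b in raw
            if a.mapped and b.mapped and a.end <= 40_000 and b.start >= 40_000 + d
        ]
        assert len(spanning) > 5
        # apparent gap = donor gap + deletion size; donor gap mean = 300 - 200
        want = 100 + d
        assert abs(np.mean(spanning) - want) <= 3 * 30 / np.sqrt(len(spanning))

    def test_inversion_straddling_pairs_are_same_strand(self, ref_one):
        donor, _ = apply_svs(ref_one, [SvSpec("INV", "chr1", 40_000, 44_000)])
        raw = simulate_read_pairs(donor, coverage=30, seed=23)
        straddle = [
            (a, b) for a, b in raw
            if a.mapped and b.mapped
            and min(a.start, b.start) < 40_000 <= max(a.start, b.start) < 44_000
        ]
        assert len(straddle) > 5
        assert all(a.strand == b.strand for a, b in straddle)

    def test_pair_count_tracks_coverage(self, ref_one):
        donor, _ = apply_svs(ref_one, [])
        raw = simulate_read_pairs(donor, read_len=100, coverage=30, seed=24)
        assert len(raw) == round(30 * 100_000 / 200)

    def test_determinism_and_input_validation(self, ref_one):
        donor, _ = apply_svs(ref_one, [])
        a = simulate_read_pairs(donor, coverage=2, seed=5)
        b = simulate_read_pairs(donor, coverage=2, seed=5)
        assert [(x.start, y.start) for x, y in a] == [(x.start, y.start) for x, y in b]
        with pytest.raises(ValueError):
            simulate_read_pairs(donor, coverage=0, seed=1)
        with pytest.raises(ValueError):
            simulate_read_pairs(donor, read_len=100, insert_mean=150, seed=1)

    def test_junction_spanning_reads_are_unmapped(self, ref_one):
        donor, _ = apply_svs(ref_one, [SvSpec("DEL", "chr1", 40_000, 45_000)])
        raw = simulate_read_pairs(donor, coverage=30, seed=25)
        unmapped = [r for p in raw for r in p if not r.mapped]
        assert unmapped  # junction-crossing reads exist at 30x
        mapped = [r for p in raw for r in p if r.mapped]
        # no mapped read may cross the deletion breakpoints
        assert all(not (r.start < 40_000 < r.end) for r in mapped)
        assert all(not (r.start < 45_000 < r.end) for r in mapped)


class TestCategorySignatures:
    """Each planted class must leave its expected anomaly categories."""

    @pytest.mark.parametrize("sv_class", simulate.SV_CLASSES)
    def test_signature_matches_expectation(self, sv_class, two_chrom_reference,
                                           eleven_class_run):
        from collections import Counter

        run = eleven_class_run
        layout = {sp.sv_class: sp for sp in run["layout"]}
        sp = layout[sv_class]
        want = Counter(simulate.EXPECTED_CATEGORIES[sv_class])
        # anomalous pairs with an anchor within 1 kb of any truth junction
        rec = next(r for r in run["truth"] if r.spec is sp)
        near = []
        for rp in run["anomalous"]:
            for read in (rp.read_a, rp.read_b):
                if any(read.chrom == c and abs(read.start - pos) < 1_000
                       for c, pos in rec.junctions):
                    near.append(rp.category)
                    break
        got = Counter(near)
        for cat in want:
            assert got[cat] >= 2, f"{sv_class}: expected {cat} support, got {got}"
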