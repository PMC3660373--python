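"""Clustering: oracle equivalence, breakpoint ranges, confidence tiers."""

import itertools

import numpy as np
import pytest

from pairsv.classify import Category, ReadAlignment, pair_anchors, triage_pair
from pairsv.cluster import (
    Cluster,
    Side,
    annotate_confidence,
    cluster_opposite_strand,
    cluster_same_strand,
    predict_breakpoints,
)
from pairsv.insert_size import InsertSizeModel

MODEL = InsertSizeModel(alpha=0.01, LC=100, UC=400, median_l=250, sd_l=58, n_obs=10_000)
D = MODEL.D  # 300


def _distance_pair(name, xplus, xminus, chrom="chr1", rl=100):
    """A DISTANCE pair with forward innermost anchor xplus and reverse
    innermost anchor xminus."""
    rp = triage_pair(
        ReadAlignment(name, chrom, xplus - rl, xplus, "+"),
        ReadAlignment(name, chrom, xminus, xminus + rl, "-", read1=False),
    )
    rp.category = Category.DISTANCE
    return rp


def _ori_pair(name, a1, a2, strand="+", chrom="chr1", rl=100):
    if strand == "+":
        r1 = ReadAlignment(name, chrom, a1 - rl, a1, "+")
        r2 = ReadAlignment(name, chrom, a2 - rl, a2, "+", read1=False)
    else:
        r1 = ReadAlignment(name, chrom, a1, a1 + rl, "-")
        r2 = ReadAlignment(name, chrom, a2, a2 + rl, "-", read1=False)
    rp = triage_pair(r1, r2)
    rp.category = Category.ORI
    return rp


def brute_force_components(anchors, D):
    """Transitive closure of the pairwise co-clustering relation by repeated
    relabelling (quadratic; the independent oracle)."""
    n = len(anchors)
    label = list(range(n))
    changed = True
    while changed:
        changed = False
        for i in range(n):
            for j in range(n):
                if (abs(anchors[i][0] - anchors[j][0]) <= D
                        and abs(anchors[i][1] - anchors[j][1]) <= D
                        and label[j] != label[i]):
                    new = min(label[i], label[j])
                    if label[i] != new or label[j] != new:
                        label[i] = label[j] = new
                        changed = True
    groups = {}
    for i, lab in enumerate(label):
        groups.setdefault(lab, set()).add(i)
    return {frozenset(g) for g in groups.values()}


class TestOppositeStrand:
    def test_two_close_pairs_form_one_cluster(self):
        pairs = [_distance_pair("a", 1_000, 6_000), _distance_pair("b", 1_040, 6_050)]
        cs = cluster_opposite_strand(pairs, MODEL, D=300)
        assert len(cs) == 1 and cs[0].S == 2

    def test_far_reverse_anchors_suppressed_as_singletons(self):
        pairs = [_distance_pair("a", 1_000, 6_000), _distance_pair("b", 1_040, 9_000)]
        cs = cluster_opposite_strand(pairs, MODEL, D=300)
        assert cs == []  # two singleton groups, both below S >= 2

    def test_mixed_categories_rejected(self):
        ok = _distance_pair("a", 1_000, 6_000)
        bad = _ori_pair("b", 2_000, 8_000)
        with pytest.raises(ValueError):
            cluster_opposite_strand([ok, bad], MODEL)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_transitive_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 200))
        xp = rng.integers(0, 4_000, n)
        xm = xp + rng.integers(400, 4_000, n)
        pairs = [_distance_pair(f"p{i}", int(xp[i]), int(xm[i])) for i in range(n)]
        cs = cluster_opposite_strand(pairs, MODEL, D=D, min_support=1)
        got = {
            frozenset(int(m.name[1:]) for m in c.members) for c in cs
        }
        want = brute_force_components(list(zip(xp.tolist(), xm.tolist())), D)
        assert got == want
        # pair-disjointness
        assert sum(len(g) for g in got) == n

    def test_order_invariance(self):
        rng = np.random.default_rng(99)
        xp = rng.integers(0, 3_000, 60)
        xm = xp + rng.integers(400, 3_000, 60)
        pairs = [_distance_pair(f"p{i}", int(xp[i]), int(xm[i])) for i in range(60)]

        def signature(ps):
            cs = cluster_opposite_strand(ps, MODEL, D=D, min_support=1)
            return {frozenset(m.name for m in c.members) for c in cs}

        shuffled = list(pairs)
        rng.shuffle(shuffled)
        assert signature(pairs) == signature(shuffled)


class TestSvFreeBackground:
    def test_sv_free_simulation_yields_almost_no_clusters(self):
        """Without rearrangements, emitted (S >= 2) clusters require two
        co-located insert-tail pairs and should be rare."""
        from pairsv import classify as cf, insert_size, simulate

        ref = simulate.simulate_reference(1, 100_000, seed=77)
        donor, _ = simulate.apply_svs(ref, [])
        pairs = [triage_pair(a, b) for a, b in
                 simulate.simulate_read_pairs(donor, coverage=10, seed=78)]
        models = insert_size.estimate_from_pairs(pairs, alpha=0.01)
        anomalous = [p for p in cf.classify_pairs(pairs, models)
                     if p.category in cf.ANOMALOUS]
        from pairsv.cluster import cluster_anomalous

        clusters = cluster_anomalous(anomalous, models.default)
        assert len(clusters) <= 3


class TestSameStrand:
    def test_forward_forward_pairs_cluster(self):
        pairs = [_ori_pair("a", 2_000, 8_000), _ori_pair("b", 2_030, 8_020)]
        cs = cluster_same_strand(pairs, MODEL, D=300)
        assert len(cs) == 1 and cs[0].S == 2
        assert cs[0].sideA.strand == "+"

    def test_opposite_orientations_stay_apart(self):
        pairs = [
            _ori_pair("a", 2_000, 8_000, "+"), _ori_pair("b", 2_030, 8_020, "+"),
            _ori_pair("c", 2_010, 8_010, "-"), _ori_pair("d", 2_040, 8_030, "-"),
        ]
        cs = cluster_same_strand(pairs, MODEL, D=300)
        assert len(cs) == 2
        assert {c.sideA.strand for c in cs} == {"+", "-"}


class TestBreakpoints:
    def test_forward_interval_formula(self):
        pairs = [_distance_pair("a", 1_000, 6_000), _distance_pair("b", 1_040, 6_050)]
        model = InsertSizeModel(0.01, 50, 350, 200, 58, 10_000)
        (c,) = cluster_opposite_strand(pairs, model, D=300)
        bpA, bpB = predict_breakpoints(c, model)
        assert bpA == (1_040, 1_350)  # [max x+, min x+ + UC)
        assert bpB == (6_050 - 350 + 1, 6_001)  # (max x- - UC, min x-]

    def test_width_non_increasing_in_support(self):
        rng = np.random.default_rng(7)
        small = [_distance_pair(f"s{i}", 1_000 + int(rng.integers(0, 50)),
                                6_000 + int(rng.integers(0, 50))) for i in range(2)]
        big = small + [
            _distance_pair(f"b{i}", 1_000 + int(rng.integers(0, 50)),
                           6_000 + int(rng.integers(0, 50))) for i in range(8)
        ]
        (c2,) = cluster_opposite_strand(small, MODEL, D=300)
        (c10,) = cluster_opposite_strand(big, MODEL, D=300)
        a2, b2 = predict_breakpoints(c2, MODEL)
        a10, b10 = predict_breakpoints(c10, MODEL)
        assert a10[1] - a10[0] <= a2[1] - a2[0]
        assert b10[1] - b10[0] <= b2[1] - b2[0]

    def test_empty_cluster_rejected(self):
        c = Cluster(Category.DISTANCE,
                    Side("chr1", "+", np.array([], dtype=int)),
                    Side("chr1", "-", np.array([], dtype=int)), members=[])
        with pytest.raises(ValueError):
            predict_breakpoints(c, MODEL)

    def test_overlapping_intervals_flagged_unreliable(self):
        pairs = [_distance_pair("a", 1_000, 1_050), _distance_pair("b", 1_020, 1_080)]
        (c,) = cluster_opposite_strand(pairs, MODEL, D=300)
        predict_breakpoints(c, MODEL)
        assert c.unreliable


class TestConfidence:
    def _cluster(self, S, span=5_000, baseq=40.0):
        pairs = [_distance_pair(f"p{i}", 1_000 + i, 1_000 + span + i)
                 for i in range(S)]
        for rp in pairs:
            object.__setattr__(rp.read_a, "baseq", baseq)
            object.__setattr__(rp.read_b, "baseq", baseq)
        (c,) = cluster_opposite_strand(pairs, MODEL, D=300)
        predict_breakpoints(c, MODEL)
        return c

    @pytest.mark.parametrize("S, tier", [(2, "low"), (4, "low"), (7, "medium"),
                                         (10, "high"), (49, "high")])
    def test_support_tiers(self, S, tier):
        c = self._cluster(S)
        annotate_confidence(c, mean_coverage=1e9)  # Poisson tail never fires
        assert c.support_tier == tier

    def test_special_support_when_exceeding_coverage(self):
        c = self._cluster(60)
        annotate_confidence(c, mean_coverage=30)
        assert c.support_tier == "special"

    @pytest.mark.parametrize("span, tier", [(100_000, "high"), (750 + 400, None),
                                            (2_000_000, "special")])
    def test_length_tiers(self, span, tier):
        # midpoint distance shrinks by ~UC relative to the anchor span;
        # craft a cluster whose predicted midpoints sit 750 bp apart
        c = self._cluster(3, span=span)
        annotate_confidence(c, mean_coverage=30)
        if tier is not None:
            assert c.length_tier == tier
        else:
            assert c.length_tier == "medium"
            assert 500 <= c.span() < 1_000

    def test_interchromosomal_clusters_have_no_length_tier(self):
        rp1 = triage_pair(ReadAlignment("a", "chr1", 900, 1000, "+"),
                          ReadAlignment("a", "chr2", 5_000, 5_100, "-", read1=False))
        rp2 = triage_pair(ReadAlignment("b", "chr1", 920, 1020, "+"),
                          ReadAlignment("b", "chr2", 5_030, 5_130, "-", read1=False))
        for rp in (rp1, rp2):
            rp.category = Category.CHRPOS
        (c,) = cluster_opposite_strand([rp1, rp2], MODEL, D=300)
        predict_breakpoints(c, MODEL)
        annotate_confidence(c, 30)
        assert c.length_tier == "n/a"

    def test_quality_tiers(self):
        annotate_confidence(self._cluster(3, baseq=40.0), 30)
        c1 = self._cluster(3, baseq=40.0)
        annotate_confidence(c1, 30)
        assert c1.q_tier == "1"
        c2 = self._cluster(3, baseq=25.0)
        annotate_confidence(c2, 30)
        assert c2.q_tier == "2"
        c3 = self._cluster(3, baseq=15.0)
        annotate_confidence(c3, 30)
        assert c3.q_tier == "lower"
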