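"""Shared fixtures: small simulated genomes run once per session."""

from __future__ import annotations

import numpy as np
import pytest

from pairsv import classify, cluster as clu, depth as dp, insert_size, simulate


def run_pr_branch(donor, seed, coverage=30.0, alpha=0.01, **sim_kw):
    """Simulate reads from a donor and run the paired-read branch in memory.

    Returns (pairs, models, anomalous, clusters, depth_reads).
    """
    raw = simulate.simulate_read_pairs(donor, coverage=coverage, seed=seed, **sim_kw)
    pairs = [classify.triage_pair(a, b) for a, b in raw]
    models = insert_size.estimate_from_pairs(pairs, alpha=alpha)
    anomalous = []
    depth_reads = []
    for rp in classify.classify_pairs(pairs, models):
        for r in (rp.read_a, rp.read_b):
            if r.mapped:
                depth_reads.append((r.chrom, r.start, r.end))
        if rp.category in classify.ANOMALOUS:
            anomalous.append(rp)
    clusters = clu.cluster_anomalous(anomalous, models.default)
    for c in clusters:
        clu.predict_breakpoints(c, models.default)
    clu.assign_ids(clusters)
    return pairs, models, anomalous, clusters, depth_reads


@pytest.fixture(scope="session")
def two_chrom_reference():
    ref = simulate.simulate_reference(2, 400_000, gc=0.45, seed=11)
    ref["chr2"] = ref["chr2"][:250_000]
    return ref


@pytest.fixture(scope="session")
def eleven_class_run(two_chrom_reference):
    """All eleven SV classes planted in one 650 kb genome at 30x."""
    ref = two_chrom_reference
    layout = simulate.default_sv_layout()
    donor, truth = simulate.apply_svs(ref, layout)
    pairs, models, anomalous, clusters, depth_reads = run_pr_branch(donor, seed=3)
    win, segs = dp.depth_pipeline(depth_reads, ref)
    return {
        "reference": ref,
        "layout": layout,
        "truth": truth,
        "models": models,
        "anomalous": anomalous,
        "clusters": clusters,
        "depth_reads": depth_reads,
        "windows": win,
        "segments": segs,
    }


@pytest.fixture(scope="session")
def eleven_class_calls(eleven_class_run):
    from pairsv import interpret as itp

    return itp.define_svs(eleven_class_run["clusters"], eleven_class_run["segments"])
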