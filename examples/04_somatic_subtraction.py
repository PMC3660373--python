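"""Somatic calling: subtract clusters shared with a matched normal.

The tumour carries a somatic deletion plus a germline inversion; the
normal carries only the inversion.  A tumour cluster is removed as soon as
one anomalous normal pair would co-cluster with it, so only the deletion
survives as a somatic call.
"""

from pairsv import classify, cluster as clu, depth, insert_size, interpret, simulate

ref = simulate.simulate_reference(1, 150_000, seed=7)
germline = simulate.SvSpec("INV", "chr1", 100_000, 104_000)
somatic = simulate.SvSpec("DEL", "chr1", 40_000, 45_000)

def pr_branch(donor, seed):
    pairs = [classify.triage_pair(a, b)
             for a, b in simulate.simulate_read_pairs(donor, coverage=30, seed=seed)]
    models = insert_size.estimate_from_pairs(pairs)
    anom, reads = [], []
    for rp in classify.classify_pairs(pairs, models):
        reads += [(r.chrom, r.start, r.end) for r in (rp.read_a, rp.read_b) if r.mapped]
        if rp.category in classify.ANOMALOUS:
            anom.append(rp)
    clusters = clu.cluster_anomalous(anom, models.default)
    for c in clusters:
        clu.predict_breakpoints(c, models.default)
    clu.assign_ids(clusters)
    return models, anom, clusters, reads

tum_donor, _ = simulate.apply_svs(ref, [somatic, germline])
nor_donor, _ = simulate.apply_svs(ref, [germline])
models, _, t_clusters, t_reads = pr_branch(tum_donor, seed=8)
_, n_anom, _, _ = pr_branch(nor_donor, seed=9)

kept = interpret.subtract_shared(t_clusters, n_anom, models.default)
print(f"tumour clusters: {len(t_clusters)}; surviving after subtraction: {len(kept)}")

_, segments = depth.depth_pipeline(t_reads, ref)
for call in interpret.define_svs(kept, segments):
    if call.defined:
        lo, hi = call.source_interval
        print(f"  somatic {call.sv_class} chr1:{lo + 1}-{hi} (depth {call.rd_state})")
print("the germline inversion is shared with the normal and is not reported")
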