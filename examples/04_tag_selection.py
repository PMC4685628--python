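"""Reduce a variant panel to LD tag SNPs by greedy set cover.

Within each LD block, markers are near-copies of each other (high r^2);
one representative per cluster carries almost all the information, which
shrinks the pairwise interaction scan quadratically.
"""

from episcreen import SimConfig, compute_ld, greedy_tag_selection, simulate_cohort

cfg = SimConfig(
    n_cases=100, n_controls=200, n_snps=300, block_size=5, within_block_r2=0.9,
    planted=[], background_prevalence=0.3, seed=5,
)
ds, _ = simulate_cohort(cfg)

for thr in (0.9, 0.8, 0.5):
    ts = greedy_tag_selection(ds, r2_threshold=thr)
    n_pairs_before = ds.n_variants * (ds.n_variants - 1) // 2
    n_pairs_after = ts.n_tags * (ts.n_tags - 1) // 2
    print(
        f"r2 >= {thr}: {ts.n_tags:3d} tags for {ds.n_variants} variants "
        f"(pair universe {n_pairs_before} -> {n_pairs_after})"
    )

ts = greedy_tag_selection(ds, r2_threshold=0.8)
vid = next(v for v in ds.variant_ids if ts.tag_of[v] != v)
ld = compute_ld(ds, vid, ts.tag_of[vid])
print(
    f"\nexample: {vid} is represented by tag {ld.id2} with observed "
    f"r^2 = {ld.r2:.3f} over {ld.n_used} co-observed samples"
)
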