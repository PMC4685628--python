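"""Run the standard GWAS quality-control cascade on a simulated cohort.

The filters and their default thresholds: sample missingness > 7%,
heterozygosity beyond mean +/- 2 SD, duplicate pairs (mean IBS >= 0.95),
PCA outliers (> 6 SD), variant missingness > 5%, MAF < 1%, and HWE exact
p < 1e-5 in controls.
"""

from episcreen import SimConfig, apply_qc, hwe_exact_test, simulate_cohort

cfg = SimConfig(
    n_cases=49, n_controls=109, n_snps=400, missing_rate=0.03,
    planted=[], background_prevalence=0.3, seed=7,
)
ds, _ = simulate_cohort(cfg)
filtered, report = apply_qc(ds)

print(report.summary())
print("\nremovals by reason:")
for frame, col in ((report.removed_samples, "sample_id"), (report.removed_variants, "variant_id")):
    for reason, grp in frame.groupby("reason"):
        print(f"  {reason}: {len(grp)} ({', '.join(grp[col].head(3))}...)")

# The HWE exact test on its own: a strong heterozygote excess in 109
# controls is vanishingly unlikely under random mating.
p_ok = hwe_exact_test(12, 48, 49)   # close to HWE proportions
p_bad = hwe_exact_test(0, 109, 0)   # every control heterozygous
print(f"\nHWE exact p, near-equilibrium table: {p_ok:.3f}")
print(f"HWE exact p, all-heterozygote table: {p_bad:.2e} (flagged as a genotyping artefact)")
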