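"""Constructed toy datasets for exercising individual QC rules."""

from __future__ import annotations

import numpy as np

from episcreen import GenotypeDataset, SampleInfo, VariantInfo
from episcreen.dataset import MISSING

QC_FIXTURE_SEED = 19  # chosen so only the planted violations trigger


def make_qc_violation_dataset(seed: int = QC_FIXTURE_SEED):
    """A cohort violating each QC filter exactly once.

    100 HWE base samples (50 cases / 50 controls) x 50 variants at MAF 0.35,
    plus three planted samples: an all-heterozygous sample (het outlier), a
    sample with 10% missing genotypes, and an exact duplicate of sample 0.
    Planted variants: column 47 with 6% missingness, column 48 carried by a
    single heterozygote (MAF 0.005 after sample QC), and column 49
    heterozygous in everyone (gross HWE violation in controls).

    Returns (dataset, expected) where expected maps reason codes to the
    planted sample/variant ids.
    """
    rng = np.random.default_rng(seed)
    n_base, n_var = 100, 50
    geno = rng.binomial(2, 0.35, size=(n_base, n_var)).astype(np.int8)
    geno[:, 48] = 0
    geno[5, 48] = 1  # single rare-allele carrier
    geno[:, 49] = 1  # universal heterozygote: HWE p ~ 0 in controls

    het_row = np.ones(n_var, dtype=np.int8)
    het_row[47] = het_row[48] = 0

    miss_row = rng.binomial(2, 0.35, size=n_var).astype(np.int8)
    miss_row[48] = 0
    miss_row[49] = 1
    miss_row[:5] = MISSING  # 10% sample missingness

    dup_row = geno[0].copy()

    geno = np.vstack([geno, het_row, miss_row, dup_row])
    geno[10:16, 47] = MISSING  # 6% variant missingness after sample QC

    samples = [
        SampleInfo(
            id=f"B{i:03d}",
            sex="female" if i % 2 else "male",
            age=40.0 + i % 20,
            status="case" if i % 2 == 0 else "control",
        )
        for i in range(n_base)
    ]
    samples.append(SampleInfo(id="HETOUT", sex="male", age=50.0, status="control"))
    samples.append(SampleInfo(id="MISSY", sex="female", age=50.0, status="case"))
    samples.append(SampleInfo(id="DUPLIC", sex="male", age=40.0, status="case"))

    variants = [
        VariantInfo(id=f"v{j:03d}", chrom="1", pos=1 + 1000 * j, allele_a="A", allele_b="G")
        for j in range(n_var)
    ]
    ds = GenotypeDataset(geno, variants, samples)
    expected = {
        "sample_missing": ["MISSY"],
        "het_outlier": ["HETOUT"],
        "duplicate": ["DUPLIC"],
        "variant_missing": ["v047"],
        "low_maf": ["v048"],
        "hwe_controls": ["v049"],
    }
    return ds, expected


def make_two_population_dataset(seed: int = 3, n_per_pop: int = 60, n_var: int = 150):
    """Two subpopulations with shifted allele frequencies, for PCA checks."""
    rng = np.random.default_rng(seed)
    f1 = rng.uniform(0.1, 0.5, size=n_var)
    f2 = np.clip(f1 + rng.choice([-0.25, 0.25], size=n_var), 0.02, 0.98)
    g1 = rng.binomial(2, f1, size=(n_per_pop, n_var))
    g2 = rng.binomial(2, f2, size=(n_per_pop, n_var))
    geno = np.vstack([g1, g2]).astype(np.int8)
    samples = [
        SampleInfo(id=f"P{i:03d}", status="control") for i in range(2 * n_per_pop)
    ]
    variants = [
        VariantInfo(id=f"m{j:03d}", pos=1 + j, allele_a="A", allele_b="G")
        for j in range(n_var)
    ]
    labels = np.array([0] * n_per_pop + [1] * n_per_pop)
    return GenotypeDataset(geno, variants, samples), labels
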