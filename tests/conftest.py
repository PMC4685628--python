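import numpy as np
import pytest

from episcreen import (
    GenotypeDataset,
    MDRConfig,
    SampleInfo,
    SimConfig,
    VariantInfo,
    make_penetrance_model,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def xor_model():
    return make_penetrance_model("xor", 0.05, 0.45, maf1=0.3, maf2=0.3)


@pytest.fixture(scope="session")
def planted_cohort(xor_model):
    """400-sample cohort (100/300) with one planted xor pair at indices 0, 100."""
    cfg = SimConfig(
        n_cases=100,
        n_controls=300,
        n_snps=201,
        planted=[(0, 100, xor_model)],
        seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """260-sample cohort with phenotype independent of every genotype."""
    cfg = SimConfig(
        n_cases=65,
        n_controls=195,
        n_snps=120,
        planted=[(0, 60, make_penetrance_model("null", 0.3, maf1=0.3, maf2=0.3))],
        seed=5,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def tiny_dataset():
    """Hand-built 6-sample x 4-variant dataset with known statistics."""
    geno = np.array(
        [
            [0, 1, 2, -1],
            [1, 1, 0, 0],
            [2, 0, 1, 0],
            [0, 2, 1, 1],
            [1, 0, 0, 2],
            [2, 1, 1, 0],
        ],
        dtype=np.int8,
    )
    variants = [
        VariantInfo(id=f"rs{j}", chrom="1", pos=100 * (j + 1), allele_a="A", allele_b="G")
        for j in range(4)
    ]
    samples = [
        SampleInfo(
            id=f"s{i}",
            sex="male" if i % 2 == 0 else "female",
            age=40.0 + i,
            status="case" if i < 3 else "control",
        )
        for i in range(6)
    ]
    return GenotypeDataset(geno, variants, samples)
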