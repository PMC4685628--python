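"""Synthetic case-control cohorts with planted two-locus epistasis.

The generator produces biallelic genotypes in Hardy-Weinberg proportions,
organised into linkage-disequilibrium blocks, with MCAR missingness and
sex/age covariates, and assigns disease status through 3x3 penetrance tables
attached to planted SNP pairs.  Cases and controls are ascertained by
rejection sampling from a latent population, mirroring a case-control study
design, so the requested cohort sizes are met exactly.

Every downstream stage of the screen (QC, tagging, association, the MDR
interaction scan) can therefore be validated against a known truth set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dataset import MISSING, GenotypeDataset, SampleInfo, VariantInfo

PENETRANCE_KINDS = ("xor", "threshold", "multiplicative", "marginal_additive", "null")

#: hard cap on latent-population draws during case/control ascertainment
MAX_DRAWS = 1_000_000

_ALLELE_PAIRS = [
    (a, b)
    for a in "ACGT"
    for b in "ACGT"
    if a < b  # minor allele lexicographically smaller: stable under freq ties
]


@dataclass(frozen=True)
class PenetranceModel:
    """A 3x3 table of P(case | g1, g2) for one planted SNP pair.

    ``table[g1, g2]`` is the disease probability given minor-allele dosages
    g1, g2 at the two loci.  ``maf1``/``maf2`` are the population minor-allele
    frequencies at those loci.
    """

    kind: str
    table: np.ndarray
    maf1: float
    maf2: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in PENETRANCE_KINDS:
            raise ValueError(f"unknown penetrance kind {self.kind!r}")
        t = np.asarray(self.table, dtype=float)
        if t.shape != (3, 3):
            raise ValueError("penetrance table must be 3x3")
        if (t < 0).any() or (t > 1).any():
            raise ValueError("penetrance entries must lie in [0, 1]")
        object.__setattr__(self, "table", t)
        for m, name in ((self.maf1, "maf1"), (self.maf2, "maf2")):
            if not (0.0 < m <= 0.5):
                raise ValueError(f"{name} must lie in (0, 0.5], got {m}")
        if self.kind == "null" and not np.allclose(t, t[0, 0]):
            raise ValueError("null model requires a constant table")
        if self.kind == "xor":
            odd = (np.add.outer(np.arange(3), np.arange(3)) % 2) == 1
            if not (t[odd].min() > t[~odd].max()):
                raise ValueError("xor model requires the checkerboard pattern")

    def penetrance(self, g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
        return self.table[np.asarray(g1), np.asarray(g2)]


def make_penetrance_model(
    kind: str,
    baseline: float,
    effect: float = 0.0,
    maf1: float = 0.3,
    maf2: float = 0.3,
    label: str = "",
) -> PenetranceModel:
    """Build a standard two-locus penetrance table.

    Parameters
    ----------
    kind
        ``null``: constant ``baseline`` everywhere (``effect`` ignored).
        ``xor``: checkerboard — cells with odd g1+g2 get ``baseline+effect``,
        the purely epistatic model with no marginal effects at MAF 0.5.
        ``threshold``: ``baseline+effect`` where both loci carry at least one
        minor allele.
        ``multiplicative``: ``effect`` is a rate ratio applied once per locus
        carrying a minor allele: ``min(1, baseline * effect**([g1>=1]+[g2>=1]))``.
        ``marginal_additive``: per-allele additive risk,
        ``baseline + effect*(g1+g2)/4`` (so the 2/2 cell reaches
        ``baseline+effect``) — a model with marginal but no interaction effect.
    baseline, effect
        Probabilities (except for ``multiplicative`` where ``effect`` is a
        ratio > 0).  ``baseline`` and, where additive, ``baseline+effect``
        must lie in [0, 1].
    """
    if kind not in PENETRANCE_KINDS:
        raise ValueError(f"unknown penetrance kind {kind!r}")
    if not (0.0 <= baseline <= 1.0):
        raise ValueError(f"baseline must lie in [0, 1], got {baseline}")
    g1, g2 = np.meshgrid(np.arange(3), np.arange(3), indexing="ij")
    if kind == "null":
        table = np.full((3, 3), baseline)
    elif kind == "multiplicative":
        if effect <= 0:
            raise ValueError("multiplicative effect must be a ratio > 0")
        n_risk = (g1 >= 1).astype(int) + (g2 >= 1).astype(int)
        table = np.minimum(1.0, baseline * effect**n_risk)
    else:
        if not (0.0 <= baseline + effect <= 1.0):
            raise ValueError(
                f"baseline+effect must lie in [0, 1], got {baseline + effect}"
            )
        if kind == "xor":
            table = np.where((g1 + g2) % 2 == 1, baseline + effect, baseline)
        elif kind == "threshold":
            table = np.where((g1 >= 1) & (g2 >= 1), baseline + effect, baseline)
        else:  # marginal_additive
            table = baseline + effect * (g1 + g2) / 4.0
    return PenetranceModel(kind=kind, table=table, maf1=maf1, maf2=maf2, label=label)


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort.

    Defaults follow the shape of a small unbalanced thyroid-carcinoma
    case-control cohort (49 cases vs 109 controls) with desk-scale variant
    counts; LD blocks of 5 markers with adjacent-marker r^2 around 0.9
    approximate the tight blocks seen on genotyping arrays.
    """

    n_cases: int = 49
    n_controls: int = 109
    n_snps: int = 1000
    block_size: int = 5
    within_block_r2: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.01
    planted: list[tuple[int, int, PenetranceModel]] = field(default_factory=list)
    background_prevalence: float = 0.0
    sex_ratio: float = 0.5  # probability of female
    age_mean: float = 50.0
    age_sd: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")
        if self.n_snps <= 0 or self.block_size <= 0:
            raise ValueError("n_snps and block_size must be positive")
        if not (0.0 <= self.within_block_r2 <= 1.0):
            raise ValueError("within_block_r2 must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        idx: list[int] = []
        blocks: set[int] = set()
        for i, j, model in self.planted:
            if i == j:
                raise ValueError("planted pair indices must be distinct")
            for k in (i, j):
                if not (0 <= k < self.n_snps):
                    raise ValueError(f"planted index {k} out of range")
                b = k // self.block_size
                if b in blocks:
                    raise ValueError(
                        "each planted SNP must lie in its own LD block"
                    )
                blocks.add(b)
            if not isinstance(model, PenetranceModel):
                raise TypeError("planted entries must carry a PenetranceModel")
            idx.extend((i, j))
        if len(set(idx)) != len(idx):
            raise ValueError("planted indices must be distinct across pairs")
        if not self.planted and self.background_prevalence <= 0:
            raise ValueError(
                "with no planted pairs, background_prevalence must be > 0 "
                "for cases to be producible"
            )


@dataclass
class TruthRecord:
    """Ground truth of a simulated cohort."""

    planted: list[tuple[int, int, PenetranceModel]]
    latent_probability: np.ndarray  # per-sample P(case) before ascertainment
    true_maf: np.ndarray  # per-variant population MAF
    flipped: np.ndarray  # variants recoded to canonical minor orientation

    def planted_ids(self, ds: GenotypeDataset) -> list[tuple[str, str]]:
        return [
            (ds.variants[i].id, ds.variants[j].id) for i, j, _ in self.planted
        ]


def _disease_probability(
    planted_genos: np.ndarray,
    models: Sequence[PenetranceModel],
    background: float,
) -> np.ndarray:
    """Noisy-OR combination of planted penetrances and background prevalence."""
    p_not = np.full(planted_genos.shape[0], 1.0 - background)
    for k, model in enumerate(models):
        g1 = planted_genos[:, 2 * k]
        g2 = planted_genos[:, 2 * k + 1]
        p_not *= 1.0 - model.penetrance(g1, g2)
    return 1.0 - p_not


def simulate_cohort(config: SimConfig) -> tuple[GenotypeDataset, TruthRecord]:
    """Simulate a case-control cohort under ``config``.

    Disease status is assigned in a latent population from the noisy-OR of
    the planted penetrance tables (plus ``background_prevalence``) and
    individuals are accepted until exactly ``n_cases`` and ``n_controls``
    are collected; exceeding the draw cap raises rather than silently
    undershooting.  Genotypes are HWE draws; within a block each variant
    copies its neighbour allele-by-allele with a flip probability tuned so
    adjacent-variant genotype r^2 targets ``within_block_r2``.  All variants
    are recoded to canonical minor-allele orientation before return and MCAR
    missingness at ``missing_rate`` is injected last.

    Returns the dataset and a :class:`TruthRecord`; byte-identical outputs
    under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls
    n_blocks = -(-config.n_snps // config.block_size)

    # Block MAFs; blocks holding a planted SNP inherit that model's MAF so
    # the planted locus has exactly the configured allele frequency.
    block_maf = rng.uniform(*config.maf_range, size=n_blocks)
    models = [m for _, _, m in config.planted]
    planted_idx: list[int] = []
    for i, j, m in config.planted:
        block_maf[i // config.block_size] = m.maf1
        block_maf[j // config.block_size] = m.maf2
        planted_idx.extend((i, j))
    true_maf = np.repeat(block_maf, config.block_size)[: config.n_snps]

    # --- ascertainment: draw planted genotypes + status until quotas met ----
    planted_mafs = np.array(
        [m for _, _, mod in config.planted for m in (mod.maf1, mod.maf2)]
    )
    acc_genos = np.empty((n, max(len(planted_idx), 1)), dtype=np.int8)
    acc_prob = np.empty(n)
    acc_status = np.empty(n, dtype=np.int8)
    got_ca = got_co = drawn = 0
    batch = 4096
    while got_ca < config.n_cases or got_co < config.n_controls:
        if drawn >= MAX_DRAWS:
            raise RuntimeError(
                f"could not ascertain {config.n_cases} cases / "
                f"{config.n_controls} controls within {MAX_DRAWS} draws; "
                "penetrance/background too extreme for the requested cohort"
            )
        m = min(batch, MAX_DRAWS - drawn)
        drawn += m
        if planted_idx:
            g = rng.binomial(2, planted_mafs, size=(m, len(planted_idx))).astype(np.int8)
            p = _disease_probability(g, models, config.background_prevalence)
        else:
            g = np.zeros((m, 1), dtype=np.int8)
            p = np.full(m, config.background_prevalence)
        is_case = rng.random(m) < p
        for t in range(m):
            if is_case[t]:
                if got_ca < config.n_cases:
                    k = got_ca + got_co
                    acc_genos[k], acc_prob[k], acc_status[k] = g[t], p[t], 1
                    got_ca += 1
            elif got_co < config.n_controls:
                k = got_ca + got_co
                acc_genos[k], acc_prob[k], acc_status[k] = g[t], p[t], 0
                got_co += 1
            if got_ca == config.n_cases and got_co == config.n_controls:
                break

    # --- genotype matrix: anchored copy-with-mutation chains per block ------
    geno = np.empty((n, config.n_snps), dtype=np.int8)
    # allele-level representation: two haplotype indicator matrices
    flip_p = 1.0 - np.sqrt(config.within_block_r2)  # r = 1 - flip_p per allele
    pos_of_planted = {idx: col for col, idx in enumerate(planted_idx)}
    for b in range(n_blocks):
        lo = b * config.block_size
        hi = min(lo + config.block_size, config.n_snps)
        maf = block_maf[b]
        anchor = next((k for k in range(lo, hi) if k in pos_of_planted), lo)
        if anchor in pos_of_planted:
            g_anchor = acc_genos[:, pos_of_planted[anchor]]
            a1 = (g_anchor == 2).astype(np.int8)
            het = g_anchor == 1
            side = rng.random(n) < 0.5
            a1 = np.where(het & side, 1, a1).astype(np.int8)
            a2 = (g_anchor - a1).astype(np.int8)
        else:
            a1 = (rng.random(n) < maf).astype(np.int8)
            a2 = (rng.random(n) < maf).astype(np.int8)
        cols = {anchor: (a1, a2)}
        for direction in (1, -1):
            prev = cols[anchor]
            rng_range = (
                range(anchor + 1, hi) if direction == 1 else range(anchor - 1, lo - 1, -1)
            )
            for k in rng_range:
                new = []
                for a in prev:
                    redraw = rng.random(n) < flip_p
                    fresh = (rng.random(n) < maf).astype(np.int8)
                    new.append(np.where(redraw, fresh, a).astype(np.int8))
                cols[k] = (new[0], new[1])
                prev = cols[k]
        for k in range(lo, hi):
            geno[:, k] = cols[k][0] + cols[k][1]

    # --- canonical minor orientation ---------------------------------------
    freq = geno.mean(axis=0) / 2.0
    flipped = freq > 0.5
    geno[:, flipped] = 2 - geno[:, flipped]

    # --- metadata -----------------------------------------------------------
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=config.n_snps)
    variants = [
        VariantInfo(
            id=f"snp{k:05d}",
            chrom="1",
            pos=1 + 5000 * k,
            allele_a=_ALLELE_PAIRS[pair_idx[k]][0],
            allele_b=_ALLELE_PAIRS[pair_idx[k]][1],
        )
        for k in range(config.n_snps)
    ]
    sex = np.where(rng.random(n) < config.sex_ratio, "female", "male")
    age = np.round(rng.normal(config.age_mean, config.age_sd, size=n), 1)
    samples = [
        SampleInfo(
            id=f"S{k:04d}",
            sex=str(sex[k]),
            age=float(age[k]),
            status="case" if acc_status[k] else "control",
        )
        for k in range(n)
    ]
    ds = GenotypeDataset(geno, variants, samples)
    if config.missing_rate > 0:
        ds = inject_missingness(ds, config.missing_rate, seed=int(rng.integers(2**31)))
    truth = TruthRecord(
        planted=list(config.planted),
        latent_probability=acc_prob.copy(),
        true_maf=true_maf.copy(),
        flipped=flipped.copy(),
    )
    return ds, truth


def inject_missingness(ds: GenotypeDataset, rate: float, seed: int) -> GenotypeDataset:
    """Set each genotype to missing independently with probability ``rate`` (MCAR)."""
    if not (0.0 <= rate < 1.0):
        raise ValueError(f"missing rate must lie in [0, 1), got {rate}")
    if rate == 0.0:
        return ds.copy()
    rng = np.random.default_rng(seed)
    mask = rng.random(ds.genotypes.shape) < rate
    g = ds.genotypes.copy()
    g[mask] = MISSING
    return GenotypeDataset(g, ds.variants, ds.samples)


# -- truth-record serialisation ---------------------------------------------


def write_truth(truth: TruthRecord, ds: GenotypeDataset, path: str) -> None:
    """Write planted pairs as TSV: ids, indices, kind, MAFs, table row-major."""
    with open(path, "w") as fh:
        fh.write(
            "snp1\tsnp2\tindex1\tindex2\tkind\tmaf1\tmaf2\t"
            + "\t".join(f"pen_{i}{j}" for i in range(3) for j in range(3))
            + "\n"
        )
        for i, j, model in truth.planted:
            cells = "\t".join(f"{x:.6g}" for x in model.table.ravel())
            fh.write(
                f"{ds.variants[i].id}\t{ds.variants[j].id}\t{i}\t{j}\t"
                f"{model.kind}\t{model.maf1:.6g}\t{model.maf2:.6g}\t{cells}\n"
            )
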