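"""Sample- and variant-level quality control for case-control genotype data.

Filters, in a fixed documented order with the conventional GWAS defaults:

1. sample missingness > 7 %
2. heterozygosity outside mean +/- 2 SD (mean/SD computed after step 1)
3. duplicate samples (mean IBS >= 0.95; the later-indexed member is dropped)
4. genotype-PCA outliers (|score| > 6 SD on any of the top 10 components)
5. variant missingness > 5 %
6. minor-allele frequency < 1 %
7. Hardy-Weinberg exact-test p < 1e-5 in controls only

Sample filters run before variant filters because MAF and HWE must be
computed on the final sample set.  Every removal carries exactly one primary
reason code in the :class:`QCReport`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset

REASON_SAMPLE_MISSING = "sample_missing"
REASON_HET_OUTLIER = "het_outlier"
REASON_DUPLICATE = "duplicate"
REASON_PCA_OUTLIER = "pca_outlier"
REASON_VARIANT_MISSING = "variant_missing"
REASON_LOW_MAF = "low_maf"
REASON_HWE = "hwe_controls"


@dataclass
class QCThresholds:
    """Filter thresholds; defaults are the screen's standard settings."""

    sample_missing_max: float = 0.07
    het_sd_mult: float = 2.0
    variant_missing_max: float = 0.05
    maf_min: float = 0.01
    hwe_p_min: float = 1e-5
    dup_ibs_min: float = 0.95
    pca_sd_mult: float = 6.0
    pca_components: int = 10

    def __post_init__(self) -> None:
        if not (0.0 <= self.sample_missing_max <= 1.0):
            raise ValueError("sample_missing_max must lie in [0, 1]")
        if not (0.0 <= self.variant_missing_max <= 1.0):
            raise ValueError("variant_missing_max must lie in [0, 1]")
        if not (0.0 <= self.maf_min <= 0.5):
            raise ValueError("maf_min must lie in [0, 0.5]")
        if not (0.0 <= self.hwe_p_min <= 1.0):
            raise ValueError("hwe_p_min must lie in [0, 1]")
        if not (0.0 < self.dup_ibs_min <= 1.0):
            raise ValueError("dup_ibs_min must lie in (0, 1]")
        if self.het_sd_mult <= 0 or self.pca_sd_mult <= 0:
            raise ValueError("SD multipliers must be positive")
        if self.pca_components < 1:
            raise ValueError("pca_components must be >= 1")


@dataclass
class QCReport:
    """Per-axis statistics and removal bookkeeping for one QC run."""

    sample_stats: pd.DataFrame
    variant_stats: pd.DataFrame
    removed_samples: pd.DataFrame  # columns: sample_id, reason
    removed_variants: pd.DataFrame  # columns: variant_id, reason
    n_samples_before: int
    n_samples_after: int
    n_variants_before: int
    n_variants_after: int
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    def summary(self) -> str:
        return (
            f"{self.n_samples_after} samples, {self.n_variants_after} SNPs "
            f"remained (removed {self.n_samples_before - self.n_samples_after} "
            f"samples, {self.n_variants_before - self.n_variants_after} SNPs)"
        )

    def write(self, prefix: str) -> None:
        self.sample_stats.to_csv(f"{prefix}.qc_samples.tsv", sep="\t", index=False)
        self.variant_stats.to_csv(f"{prefix}.qc_variants.tsv", sep="\t", index=False)
        with open(f"{prefix}.qc_summary.txt", "w") as fh:
            fh.write(self.summary() + "\n")
            for _, row in self.removed_samples.iterrows():
                fh.write(f"removed sample\t{row.sample_id}\t{row.reason}\n")
            for _, row in self.removed_variants.iterrows():
                fh.write(f"removed variant\t{row.variant_id}\t{row.reason}\n")


# ---------------------------------------------------------------------------
# per-sample statistics
# ---------------------------------------------------------------------------


def sample_stats(ds: GenotypeDataset) -> pd.DataFrame:
    """Per-sample missing rate and heterozygosity rate.

    ``missing_rate`` = missing cells / variants; ``het_rate`` = fraction of
    heterozygous calls among non-missing genotypes (NaN for a fully missing
    sample, which is removed by the missingness filter anyway).
    """
    if ds.n_samples == 0 or ds.n_variants == 0:
        raise ValueError("dataset must be non-empty")
    g = ds.genotypes
    miss = (g == MISSING).sum(axis=1)
    obs = ds.n_variants - miss
    het = (g == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_rate = np.where(obs > 0, het / np.maximum(obs, 1), np.nan)
    return pd.DataFrame(
        {
            "sample_id": ds.sample_ids,
            "missing_rate": miss / ds.n_variants,
            "het_rate": het_rate,
        }
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test (two-sided, no mid-p).

    Conditions on the observed allele counts and sums, over all heterozygote
    counts of the same parity, the probabilities of tables no more probable
    than the observed one.  Probabilities are computed as exact integer
    weights w(h) = n! / (nAA(h)! h! naa(h)!) * 2^h, so the comparison and the
    resulting p-value are exact up to the final float division.
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0 or int(c) != c:
            raise ValueError("genotype counts must be non-negative integers")
    n_AA, n_Aa, n_aa = int(n_AA), int(n_Aa), int(n_aa)
    n = n_AA + n_Aa + n_aa
    if n == 0:
        return 1.0
    n_a = 2 * n_AA + n_Aa  # rarer-or-not, symmetry makes the choice moot
    n_b = 2 * n_aa + n_Aa
    n_minor = min(n_a, n_b)

    def weight(h: int) -> int:
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        return (
            math.factorial(n)
            // (math.factorial(hom_minor) * math.factorial(h) * math.factorial(hom_major))
            * 2**h
        )

    w_obs = weight(n_Aa)
    total = 0
    tail = 0
    for h in range(n_minor % 2, n_minor + 1, 2):
        w = weight(h)
        total += w
        if w <= w_obs:
            tail += w
    return tail / total


def hwe_controls(ds: GenotypeDataset) -> np.ndarray:
    """HWE exact-test p per variant, computed in control samples only."""
    g = ds.genotypes[~ds.case_mask]
    out = np.empty(ds.n_variants)
    for j in range(ds.n_variants):
        col = g[:, j]
        out[j] = hwe_exact_test(
            int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum())
        )
    return out


# ---------------------------------------------------------------------------
# duplicates
# ---------------------------------------------------------------------------


def detect_duplicates(
    ds: GenotypeDataset, dup_ibs_min: float = 0.95
) -> tuple[list[tuple[str, str, float]], list[tuple[str, str]]]:
    """Find near-duplicate sample pairs by mean identity-by-state.

    For each pair, s = mean over co-observed variants of (2 - |g_i - g_j|)/2;
    pairs with s >= ``dup_ibs_min`` are returned as (id_i, id_j, s) with
    i < j.  Pairs with zero co-observed variants have undefined similarity
    and are reported separately.
    """
    if ds.n_samples < 2:
        raise ValueError("need at least two samples")
    g = ds.genotypes.astype(np.float64)
    obs = g >= 0
    g0 = np.where(obs, g, 0.0)
    dups: list[tuple[str, str, float]] = []
    undefined: list[tuple[str, str]] = []
    # chunked pairwise pass keeps memory at O(chunk * n * V)
    for i in range(ds.n_samples - 1):
        co = obs[i] & obs[i + 1 :]
        n_co = co.sum(axis=1)
        diff = np.abs(g0[i] - g0[i + 1 :]) * co
        with np.errstate(invalid="ignore", divide="ignore"):
            s = (2.0 * n_co - diff.sum(axis=1)) / (2.0 * n_co)
        for k in np.nonzero(n_co == 0)[0]:
            undefined.append((ds.samples[i].id, ds.samples[i + 1 + k].id))
        for k in np.nonzero((n_co > 0) & (s >= dup_ibs_min))[0]:
            dups.append(
                (ds.samples[i].id, ds.samples[i + 1 + k].id, float(s[k]))
            )
    return dups, undefined


# ---------------------------------------------------------------------------
# genotype PCA
# ---------------------------------------------------------------------------


def genotype_pca(
    ds: GenotypeDataset, k: int = 10, sd_mult: float = 6.0
) -> tuple[np.ndarray, np.ndarray]:
    """Standardised genotype PCA with SD-based outlier flags.

    Columns are centred by 2*MAF and scaled by sqrt(2*MAF*(1-MAF)) (the
    usual binomial standardisation); missing genotypes contribute 0 after
    centring.  Monomorphic variants are excluded with a warning.  Returns
    (scores, outlier) where scores has shape (n_samples, k) and outlier
    flags samples with |score| > sd_mult * SD on any component.
    """
    if ds.n_samples < 2:
        raise ValueError("need at least two samples for PCA")
    g = ds.genotypes.astype(np.float64)
    obs = g >= 0
    with np.errstate(invalid="ignore"):
        freq = np.where(g >= 0, g, 0).sum(axis=0) / (2.0 * np.maximum(obs.sum(axis=0), 1))
    poly = (freq > 0) & (freq < 1) & (obs.sum(axis=0) > 0)
    if not poly.all():
        warnings.warn(
            f"excluding {int((~poly).sum())} monomorphic/unobserved variants from PCA"
        )
    if poly.sum() == 0:
        raise ValueError("no polymorphic variants available for PCA")
    k = min(k, ds.n_samples - 1, int(poly.sum()))
    f = freq[poly]
    x = (np.where(g >= 0, g, 0)[:, poly] - 2 * f) / np.sqrt(2 * f * (1 - f))
    x[~obs[:, poly]] = 0.0
    x -= x.mean(axis=0)  # row-centred matrix: PCs of sample covariance
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :k] * s[:k]
    sd = scores.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf
    outlier = (np.abs(scores) > sd_mult * sd).any(axis=1)
    return scores, outlier


# ---------------------------------------------------------------------------
# the full filter cascade
# ---------------------------------------------------------------------------


def _variant_stats_frame(ds: GenotypeDataset) -> pd.DataFrame:
    g = ds.genotypes
    miss = (g == MISSING).mean(axis=0)
    return pd.DataFrame(
        {
            "variant_id": ds.variant_ids,
            "missing_rate": miss,
            "maf": ds.maf(),
            "hwe_p_controls": hwe_controls(ds),
        }
    )


def apply_qc(
    ds: GenotypeDataset, thresholds: QCThresholds | None = None
) -> tuple[GenotypeDataset, QCReport]:
    """Run the full QC cascade and return the filtered dataset plus report.

    See the module docstring for the filter order.  Raises if any step
    empties the dataset.
    """
    th = thresholds or QCThresholds()
    n_s0, n_v0 = ds.n_samples, ds.n_variants
    removed_s: list[tuple[str, str]] = []
    removed_v: list[tuple[str, str]] = []

    stats0 = sample_stats(ds)

    # (1) sample missingness
    drop = stats0.missing_rate > th.sample_missing_max
    removed_s += [(sid, REASON_SAMPLE_MISSING) for sid in stats0.sample_id[drop]]
    cur = ds.subset(sample_idx=np.nonzero(~drop.to_numpy())[0])
    _check_nonempty(cur, "sample missingness")

    # (2) heterozygosity outliers: mean/SD on post-step-1 samples
    if np.isfinite(th.het_sd_mult):
        het = sample_stats(cur).het_rate.to_numpy()
        mu, sd = np.nanmean(het), np.nanstd(het, ddof=1)
        if np.isfinite(sd) and sd > 0:
            out = np.abs(het - mu) > th.het_sd_mult * sd
            out &= np.isfinite(het)
            removed_s += [
                (cur.samples[i].id, REASON_HET_OUTLIER) for i in np.nonzero(out)[0]
            ]
            cur = cur.subset(sample_idx=np.nonzero(~out)[0])
            _check_nonempty(cur, "heterozygosity")

    # (3) duplicates: drop the later-indexed member of each flagged pair
    undefined_pairs: list[tuple[str, str]] = []
    if cur.n_samples >= 2:
        dups, undefined_pairs = detect_duplicates(cur, th.dup_ibs_min)
        drop_ids = {b for _a, b, _s in dups}
        if drop_ids:
            removed_s += [(sid, REASON_DUPLICATE) for sid in cur.sample_ids if sid in drop_ids]
            keep = [i for i, sid in enumerate(cur.sample_ids) if sid not in drop_ids]
            cur = cur.subset(sample_idx=keep)
            _check_nonempty(cur, "duplicate removal")

    # (4) PCA outliers
    if cur.n_samples > 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                _scores, outlier = genotype_pca(
                    cur, k=th.pca_components, sd_mult=th.pca_sd_mult
                )
            except ValueError:
                outlier = np.zeros(cur.n_samples, dtype=bool)
        if outlier.any():
            removed_s += [
                (cur.samples[i].id, REASON_PCA_OUTLIER) for i in np.nonzero(outlier)[0]
            ]
            cur = cur.subset(sample_idx=np.nonzero(~outlier)[0])
            _check_nonempty(cur, "PCA outliers")

    # variant statistics on the final sample set
    vstats = _variant_stats_frame(cur)
    miss = vstats.missing_rate.to_numpy()
    maf = vstats.maf.to_numpy()
    hwe_p = vstats.hwe_p_controls.to_numpy()

    reason = np.array([""] * cur.n_variants, dtype=object)
    reason[(reason == "") & (miss > th.variant_missing_max)] = REASON_VARIANT_MISSING
    with np.errstate(invalid="ignore"):
        # unobserved variants count as low-MAF only when the filter is active
        low_maf = np.where(np.isnan(maf), th.maf_min > 0, maf < th.maf_min)
    reason[(reason == "") & low_maf] = REASON_LOW_MAF
    reason[(reason == "") & (hwe_p < th.hwe_p_min)] = REASON_HWE
    keep_v = reason == ""
    removed_v += [
        (cur.variants[j].id, reason[j]) for j in np.nonzero(~keep_v)[0]
    ]
    out_ds = cur.subset(variant_idx=np.nonzero(keep_v)[0])
    _check_nonempty(out_ds, "variant filters")

    report = QCReport(
        sample_stats=stats0,
        variant_stats=vstats,
        removed_samples=pd.DataFrame(removed_s, columns=["sample_id", "reason"]),
        removed_variants=pd.DataFrame(removed_v, columns=["variant_id", "reason"]),
        n_samples_before=n_s0,
        n_samples_after=out_ds.n_samples,
        n_variants_before=n_v0,
        n_variants_after=out_ds.n_variants,
        undefined_pairs=undefined_pairs,
    )
    return out_ds, report


def _check_nonempty(ds: GenotypeDataset, stage: str) -> None:
    if ds.n_samples == 0 or ds.n_variants == 0:
        raise ValueError(f"dataset empty after QC step: {stage}")
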