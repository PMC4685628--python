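"""Tag-SNP selection by pairwise linkage disequilibrium.

Reduces a QC-passed variant panel to a set of LD representatives: a greedy
set cover per chromosome in which, repeatedly, the uncovered variant that
covers the most uncovered variants (r^2 >= threshold within a base-pair
window) becomes a tag, ties broken by smaller genomic position.  r^2 is the
squared Pearson correlation of genotype dosages over co-observed samples
(composite LD) — deterministic on unphased data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataset import GenotypeDataset


@dataclass(frozen=True)
class LDResult:
    """r^2 between one variant pair, with the co-observed sample count."""

    id1: str
    id2: str
    r2: float
    n_used: int


@dataclass
class TagSet:
    """Chosen tags, the covered-variant -> tag mapping, and the observed r^2."""

    tags: list[str]
    tag_of: dict[str, str]
    tag_r2: dict[str, float]
    r2_threshold: float
    window_bp: int

    @property
    def n_tags(self) -> int:
        return len(self.tags)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("variant_id\ttag_id\tr2\n")
            for vid, tid in self.tag_of.items():
                fh.write(f"{vid}\t{tid}\t{self.tag_r2[vid]:.4f}\n")


def genotype_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over co-observed samples.

    Returns NaN (undefined) if fewer than two samples are co-observed or
    either variant is monomorphic among them; callers treating NaN as "not
    in LD" should map it to 0.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("dosage vectors must have the same length")
    co = (g1 >= 0) & (g2 >= 0)
    if co.sum() < 2:
        return float("nan")
    x, y = g1[co], g2[co]
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def compute_ld(ds: GenotypeDataset, id1: str, id2: str) -> LDResult:
    """LD between two named variants as an :class:`LDResult` record."""
    g1 = ds.genotypes[:, ds.variant_index(id1)]
    g2 = ds.genotypes[:, ds.variant_index(id2)]
    n_used = int(((g1 >= 0) & (g2 >= 0)).sum())
    return LDResult(id1=id1, id2=id2, r2=genotype_r2(g1, g2), n_used=n_used)


def pairwise_r2(ds: GenotypeDataset, idx: np.ndarray | None = None) -> np.ndarray:
    """Dense r^2 matrix among the given variant columns (NaN where undefined).

    Vectorised masked-correlation: exact pairwise-complete Pearson r^2,
    matching :func:`genotype_r2` entry-by-entry.
    """
    g = ds.genotypes.astype(np.float64)
    if idx is not None:
        g = g[:, np.asarray(idx)]
    obs = (g >= 0).astype(np.float64)
    gz = np.where(g >= 0, g, 0.0)
    n = obs.T @ obs  # co-observed counts
    s1 = gz.T @ obs  # sum of x over co-observed
    s2 = obs.T @ gz  # sum of y over co-observed
    s11 = (gz * gz).T @ obs
    s22 = obs.T @ (gz * gz)
    s12 = gz.T @ gz
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = s12 - s1 * s2 / n
        v1 = s11 - s1 * s1 / n
        v2 = s22 - s2 * s2 / n
        r2 = (cov * cov) / (v1 * v2)
    r2[(n < 2) | (v1 <= 0) | (v2 <= 0)] = np.nan
    return r2


def greedy_tag_selection(
    ds: GenotypeDataset, r2_threshold: float = 0.8, window_bp: int = 250_000
) -> TagSet:
    """Select tag SNPs by greedy set cover per chromosome.

    Coverage: variant u covers variant v if |pos_u - pos_v| <= window_bp on
    the same chromosome and observed r^2(u, v) >= ``r2_threshold`` (every
    variant covers itself).  Undefined r^2 counts as no coverage.  The pick
    order (most uncovered covered, then smaller position, then id) is total,
    so the result is deterministic.
    """
    if not (0.0 <= r2_threshold <= 1.0):
        raise ValueError("r2_threshold must lie in [0, 1]")
    tags: list[str] = []
    tag_of: dict[str, str] = {}
    tag_r2: dict[str, float] = {}
    by_chrom: dict[str, list[int]] = {}
    for j, v in enumerate(ds.variants):
        by_chrom.setdefault(v.chrom, []).append(j)

    for chrom in sorted(by_chrom):
        idx = np.array(by_chrom[chrom])
        pos = np.array([ds.variants[j].pos for j in idx])
        order = np.lexsort(([ds.variants[j].id for j in idx], pos))
        idx, pos = idx[order], pos[order]
        m = len(idx)
        r2 = pairwise_r2(ds, idx)
        near = np.abs(pos[:, None] - pos[None, :]) <= window_bp
        with np.errstate(invalid="ignore"):
            covers = near & (np.nan_to_num(r2, nan=-1.0) >= r2_threshold)
        np.fill_diagonal(covers, True)

        uncovered = np.ones(m, dtype=bool)
        while uncovered.any():
            # candidate tags are themselves uncovered
            gain = np.where(uncovered, (covers & uncovered[None, :]).sum(axis=1), -1)
            best = int(np.argmax(gain))  # rows are position-sorted: first max wins
            tid = ds.variants[idx[best]].id
            tags.append(tid)
            newly = covers[best] & uncovered
            for k in np.nonzero(newly)[0]:
                vid = ds.variants[idx[k]].id
                tag_of[vid] = tid
                tag_r2[vid] = 1.0 if k == best else float(r2[best, k])
            uncovered &= ~newly
    return TagSet(
        tags=tags,
        tag_of=tag_of,
        tag_r2=tag_r2,
        r2_threshold=r2_threshold,
        window_bp=window_bp,
    )
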