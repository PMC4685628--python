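"""Single-SNP association stage: allelic tests, odds ratios, covariate-adjusted
logistic models, BH-FDR adjustment and QQ/genomic-control diagnostics.

Two complementary association routes are provided, the standard pair used for
a case-control genotype screen: a 1-df allelic chi-square on the 2x2 allele
count table, and an additive-coded logistic model adjusted for sex and age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .dataset import GenotypeDataset

#: median of the 1-df chi-square distribution, the genomic-control reference
CHI2_1DF_MEDIAN = float(sps.chi2.ppf(0.5, 1))


@dataclass
class AssociationResult:
    """Per-SNP allelic association summary (one Table-2-style row)."""

    variant_id: str
    gene: Optional[str]
    freq_cases: float
    freq_controls: float
    counts: tuple[int, int, int, int]  # minor/major in cases, minor/major in controls
    odds_ratio: float
    ci95: tuple[float, float]
    p_nominal: float
    p_adjusted: float = float("nan")
    test: str = "allelic_chisq"


@dataclass
class AssocSummary:
    """Genomic-control lambda plus QQ and Manhattan plot coordinates."""

    lambda_gc: float
    qq_expected: np.ndarray  # -log10 expected quantiles, ascending
    qq_observed: np.ndarray  # -log10 observed p, ascending
    manhattan: Optional[pd.DataFrame] = None  # chrom, pos, neg_log10_p


# ---------------------------------------------------------------------------
# allele counting
# ---------------------------------------------------------------------------


def allele_table(ds: GenotypeDataset, variant_id: str) -> tuple[int, int, int, int]:
    """2x2 allele counts (minor_cases, major_cases, minor_controls, major_controls).

    Each non-missing genotype contributes two alleles.  Raises if either
    status group has no genotyped sample at the variant.
    """
    j = ds.variant_index(variant_id)
    g = ds.genotypes[:, j]
    case = ds.case_mask
    out = []
    for grp, name in ((case, "cases"), (~case, "controls")):
        col = g[grp]
        col = col[col >= 0]
        if col.size == 0:
            raise ValueError(
                f"variant {variant_id}: no genotyped samples in {name}"
            )
        minor = int(col.sum())
        out += [minor, int(2 * col.size - minor)]
    return tuple(out)  # type: ignore[return-value]


def allele_frequencies(counts: tuple[int, int, int, int]) -> tuple[float, float]:
    """Minor-allele frequency in cases and controls from a 2x2 count table."""
    a, b, c, d = counts
    return a / (a + b), c / (c + d)


# ---------------------------------------------------------------------------
# odds ratios
# ---------------------------------------------------------------------------


def odds_ratio(freq_cases: float, freq_controls: float) -> float:
    """Allelic odds ratio from the two group frequencies.

    OR = [f_ca/(1-f_ca)] / [f_co/(1-f_co)]; both frequencies must lie
    strictly inside (0, 1).
    """
    for f, name in ((freq_cases, "freq_cases"), (freq_controls, "freq_controls")):
        if not (0.0 < f < 1.0):
            raise ValueError(f"{name} must lie in (0, 1), got {f}")
    return (freq_cases / (1.0 - freq_cases)) / (freq_controls / (1.0 - freq_controls))


def odds_ratio_counts(
    counts: tuple[int, int, int, int], continuity: bool = False
) -> tuple[float, tuple[float, float]]:
    """Odds ratio with Woolf 95% CI from a 2x2 count table (a, b, c, d).

    OR = ad/bc and CI = exp(ln OR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d)).
    With a zero cell the CI (and OR) are undefined unless ``continuity``
    enables the Haldane-Anscombe +0.5 correction on every cell.
    """
    a, b, c, d = (float(x) for x in counts)
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if min(a, b, c, d) == 0:
        if not continuity:
            raise ValueError(
                "zero cell in 2x2 table: OR/CI undefined without continuity "
                "correction (pass continuity=True)"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(or_) - 1.96 * se), np.exp(np.log(or_) + 1.96 * se)
    return float(or_), (float(lo), float(hi))


# ---------------------------------------------------------------------------
# allelic chi-square
# ---------------------------------------------------------------------------


def allelic_test(counts: tuple[int, int, int, int]) -> tuple[float, float]:
    """1-df Pearson chi-square on the 2x2 allele table, no continuity correction.

    Returns (statistic, p).  A zero margin (empty row or column) yields
    (0, 1) by convention.
    """
    a, b, c, d = (float(x) for x in counts)
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty 2x2 table")
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 0.0, 1.0
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(stat), float(sps.chi2.sf(stat, 1))


# ---------------------------------------------------------------------------
# covariate-adjusted logistic model
# ---------------------------------------------------------------------------


def logistic_assoc(
    ds: GenotypeDataset,
    variant_ids: Optional[Sequence[str]] = None,
    covariates: Sequence[str] = ("sex", "age"),
    tol: float = 1e-8,
    maxiter: int = 50,
) -> pd.DataFrame:
    """Additive-coded logistic association, optionally sex/age adjusted.

    Fits status ~ dosage (+ sex + age) per variant by IRLS and reports the
    Wald p for the dosage term.  Samples with a missing genotype, or missing
    age when age is a covariate, are dropped per variant.  Monomorphic
    genotype columns and non-converged/separated fits are flagged
    (``ok=False``) with NaN estimates.

    Returns a DataFrame with columns variant_id, beta, se, p, ok.
    """
    ids = list(variant_ids) if variant_ids is not None else ds.variant_ids
    y_all = ds.status_array.astype(float)
    sex = np.array([1.0 if s.sex == "female" else 0.0 for s in ds.samples])
    age = np.array([s.age for s in ds.samples])
    rows = []
    for vid in ids:
        j = ds.variant_index(vid)
        g = ds.genotypes[:, j].astype(float)
        keep = g >= 0
        cols = [g]
        if "sex" in covariates:
            cols.append(sex)
        if "age" in covariates:
            cols.append(age)
            keep &= np.isfinite(age)
        x = np.column_stack(cols)[keep]
        y = y_all[keep]
        if x.shape[0] == 0 or np.ptp(x[:, 0]) == 0 or np.ptp(y) == 0:
            rows.append((vid, np.nan, np.nan, np.nan, False))
            continue
        X = sm.add_constant(x, has_constant="add")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                    tol=tol, maxiter=maxiter
                )
            converged = bool(res.converged) and np.isfinite(res.bse[1])
            # huge SE is the classic quasi-separation signature
            if converged and res.bse[1] > 1e3:
                converged = False
            if not converged:
                rows.append((vid, np.nan, np.nan, np.nan, False))
                continue
            beta, se = float(res.params[1]), float(res.bse[1])
            p = float(2.0 * sps.norm.sf(abs(beta / se)))
            rows.append((vid, beta, se, p, True))
        except (PerfectSeparationWarning, Exception):
            rows.append((vid, np.nan, np.nan, np.nan, False))
    return pd.DataFrame(rows, columns=["variant_id", "beta", "se", "p", "ok"])


# ---------------------------------------------------------------------------
# multiple testing and diagnostics
# ---------------------------------------------------------------------------


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def qq_lambda(
    p_values: Sequence[float], positions: Optional[pd.DataFrame] = None
) -> AssocSummary:
    """Genomic-control lambda and QQ coordinates for a set of p-values.

    lambda_gc = median(qchisq_1(1 - p)) / 0.4549...; expected -log10
    quantiles are -log10((i - 0.5)/m).  ``positions`` (chrom, pos) may be
    supplied to also emit Manhattan coordinates in the given variant order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 10:
        raise ValueError("need at least 10 p-values")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi = sps.chi2.isf(p, 1)
    lam = float(np.median(chi) / CHI2_1DF_MEDIAN)
    m = p.size
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)[::-1]
    observed = -np.log10(np.sort(p)[::-1])
    manhattan = None
    if positions is not None:
        manhattan = positions.copy()
        manhattan["neg_log10_p"] = -np.log10(p)
    return AssocSummary(
        lambda_gc=lam, qq_expected=expected, qq_observed=observed, manhattan=manhattan
    )


# ---------------------------------------------------------------------------
# whole-panel driver
# ---------------------------------------------------------------------------


def associate_all(
    ds: GenotypeDataset,
    variant_ids: Optional[Sequence[str]] = None,
    continuity: bool = False,
) -> list[AssociationResult]:
    """Allelic chi-square association for a panel of variants, BH-adjusted.

    Variants where a status group has no genotyped sample are skipped with a
    warning; OR/CI fall back to the continuity-corrected estimate when a
    zero cell would otherwise leave them undefined.
    """
    ids = list(variant_ids) if variant_ids is not None else ds.variant_ids
    results: list[AssociationResult] = []
    for vid in ids:
        try:
            counts = allele_table(ds, vid)
        except ValueError as exc:
            warnings.warn(str(exc))
            continue
        f_ca, f_co = allele_frequencies(counts)
        try:
            or_, ci = odds_ratio_counts(counts, continuity=continuity)
        except ValueError:
            or_, ci = odds_ratio_counts(counts, continuity=True)
        stat, p = allelic_test(counts)
        v = ds.variants[ds.variant_index(vid)]
        results.append(
            AssociationResult(
                variant_id=vid,
                gene=v.gene,
                freq_cases=f_ca,
                freq_controls=f_co,
                counts=counts,
                odds_ratio=or_,
                ci95=ci,
                p_nominal=p,
            )
        )
    if results:
        adj = bh_adjust([r.p_nominal for r in results])
        for r, q in zip(results, adj):
            r.p_adjusted = float(q)
    return results
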