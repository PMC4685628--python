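"""Exhaustive pairwise Multifactor-Dimensionality Reduction (MDR).

For every SNP pair, the nine two-locus genotype cells are pooled into
high-risk / low-risk classes by their training case:control ratio, turning
the 3x3 genotype space into a one-dimensional classifier.  Each pair is
scored by stratified 10-fold cross-validation: the cross-validation value
(CVV) is the mean held-out *balanced* accuracy, (sensitivity +
specificity)/2, so a chance classifier scores 0.5 regardless of the
case:control imbalance of the cohort.  Pairs with CVV strictly above the
significance threshold (default 0.5) are flagged.

The scan over all pairs is a pure map: results are identical for any worker
count, and ranking ties are broken lexicographically on the variant ids so
the output is fully deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from numba import njit

from .dataset import GenotypeDataset

HIGH, LOW, EMPTY = 1, 0, -1

_POLICIES = ("low_risk", "unknown_misclassified")


@dataclass
class MDRConfig:
    """Settings for the pairwise MDR scan.

    ``ratio_threshold`` is the case:control ratio T above which a genotype
    cell is labelled high-risk; ``None`` (the default) uses the training
    fold's overall case:control ratio, the standard choice for unbalanced
    cohorts.  ``empty_cell_policy`` governs held-out samples falling in a
    training-empty cell or lacking a genotype: ``low_risk`` predicts
    control (deterministic, conservative), ``unknown_misclassified`` counts
    them as errors.
    """

    n_folds: int = 10
    ratio_threshold: Optional[float] = None
    empty_cell_policy: str = "low_risk"
    cvv_threshold: float = 0.5
    top_n: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not (0.0 <= self.cvv_threshold <= 1.0):
            raise ValueError("cvv_threshold must lie in [0, 1]")
        if self.ratio_threshold is not None and self.ratio_threshold <= 0:
            raise ValueError("ratio_threshold must be positive")
        if self.empty_cell_policy not in _POLICIES:
            raise ValueError(f"empty_cell_policy must be one of {_POLICIES}")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")


@dataclass
class RiskGrid:
    """3x3 risk labels (1 high, 0 low, -1 empty) with training cell counts."""

    labels: np.ndarray
    case_counts: np.ndarray
    control_counts: np.ndarray


@dataclass
class MDRModel:
    """One SNP pair's cross-validated MDR result."""

    id1: str
    id2: str
    gene1: Optional[str]
    gene2: Optional[str]
    fold_grids: list[RiskGrid]
    train_ba: np.ndarray
    test_ba: np.ndarray
    cvv: float
    significant: bool


@dataclass
class ScanResult:
    """Ranked scan output: detailed top models plus the full CVV table."""

    models: list[MDRModel]
    table: pd.DataFrame  # columns id1, id2, cvv — ranked
    config: MDRConfig

    @property
    def mean_cvv(self) -> float:
        return float(self.table.cvv.mean())


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------


def make_folds(status: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Stratified fold assignment: per-class counts differ by at most 1.

    ``status`` is 1 for cases, 0 for controls.  Deterministic under seed.
    """
    status = np.asarray(status)
    rng = np.random.default_rng(seed)
    fold = np.empty(status.shape[0], dtype=np.int64)
    for cls in (1, 0):
        idx = np.nonzero(status == cls)[0]
        if idx.size < n_folds:
            raise ValueError(
                f"need at least {n_folds} samples of class {cls}, got {idx.size}"
            )
        perm = rng.permutation(idx)
        fold[perm] = np.arange(perm.size) % n_folds
    return fold


# ---------------------------------------------------------------------------
# risk grids
# ---------------------------------------------------------------------------


def _label_cell(ca: int, co: int, t_num: int, t_den: int, fixed_t: float) -> int:
    """Risk label for one cell; fixed_t < 0 means use ratio t_num/t_den."""
    if ca == 0 and co == 0:
        return EMPTY
    if co == 0:
        return HIGH  # infinite ratio convention
    if fixed_t >= 0:
        return HIGH if ca >= fixed_t * co else LOW
    return HIGH if ca * t_den >= co * t_num else LOW


def fit_risk_grid(
    g1: np.ndarray, g2: np.ndarray, status: np.ndarray, T: float
) -> RiskGrid:
    """Fit a 3x3 risk grid on training data at a fixed ratio threshold T.

    Samples missing either genotype are excluded from counting.  A cell is
    high-risk iff its case:control ratio is >= T (cases with no controls ->
    high); cells with no samples are labelled empty.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    status = np.asarray(status)
    ok = (g1 >= 0) & (g2 >= 0)
    cell = 3 * g1[ok] + g2[ok]
    s = status[ok]
    ca = np.bincount(cell[s == 1], minlength=9).reshape(3, 3)
    co = np.bincount(cell[s == 0], minlength=9).reshape(3, 3)
    labels = np.empty((3, 3), dtype=np.int8)
    for i in range(3):
        for j in range(3):
            labels[i, j] = _label_cell(int(ca[i, j]), int(co[i, j]), 0, 0, T)
    return RiskGrid(labels=labels, case_counts=ca, control_counts=co)


# ---------------------------------------------------------------------------
# the cross-validation kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _eval_cells(
    cells, status, fold_ids, n_folds, policy_mis, fixed_t, train_ba, test_ba
):  # pragma: no cover - exercised via wrappers
    """CVV for one pair; fills per-fold train/test balanced accuracies.

    ``cells`` holds 3*g1+g2 in 0..8, or -1 when either genotype is missing.
    ``fixed_t`` < 0 selects the training-fold case:control ratio threshold
    (compared by exact integer cross-multiplication).
    """
    n = cells.shape[0]
    ca = np.zeros((n_folds, 9), dtype=np.int64)
    co = np.zeros((n_folds, 9), dtype=np.int64)
    ca_all = np.zeros(9, dtype=np.int64)
    co_all = np.zeros(9, dtype=np.int64)
    fold_ca = np.zeros(n_folds, dtype=np.int64)
    fold_co = np.zeros(n_folds, dtype=np.int64)
    mis_ca = np.zeros(n_folds, dtype=np.int64)
    mis_co = np.zeros(n_folds, dtype=np.int64)
    for i in range(n):
        f = fold_ids[i]
        c = cells[i]
        if status[i] == 1:
            fold_ca[f] += 1
            if c >= 0:
                ca[f, c] += 1
                ca_all[c] += 1
            else:
                mis_ca[f] += 1
        else:
            fold_co[f] += 1
            if c >= 0:
                co[f, c] += 1
                co_all[c] += 1
            else:
                mis_co[f] += 1
    tot_ca = fold_ca.sum()
    tot_co = fold_co.sum()
    tot_mis_ca = mis_ca.sum()
    tot_mis_co = mis_co.sum()

    cvv_sum = 0.0
    for f in range(n_folds):
        tr_ca_grid = 0
        tr_co_grid = 0
        for c in range(9):
            tr_ca_grid += ca_all[c] - ca[f, c]
            tr_co_grid += co_all[c] - co[f, c]
        tp_tr = 0
        tn_tr = 0
        tp_te = 0
        tn_te = 0
        for c in range(9):
            tca = ca_all[c] - ca[f, c]
            tco = co_all[c] - co[f, c]
            if tca == 0 and tco == 0:
                lab = -1
            elif tco == 0:
                lab = 1
            elif fixed_t >= 0.0:
                lab = 1 if tca >= fixed_t * tco else 0
            else:
                lab = 1 if tca * tr_co_grid >= tco * tr_ca_grid else 0
            if lab == 1:
                tp_tr += tca
                tp_te += ca[f, c]
            elif lab == 0:
                tn_tr += tco
                tn_te += co[f, c]
            else:  # empty in training
                if not policy_mis:  # low_risk: predicted control
                    tn_te += co[f, c]
        if not policy_mis:  # missing-genotype samples predicted control
            tn_tr += tot_mis_co - mis_co[f]
            tn_te += mis_co[f]
        tr_n_ca = tot_ca - fold_ca[f]
        tr_n_co = tot_co - fold_co[f]
        if tr_n_ca > 0 and tr_n_co > 0:
            train_ba[f] = (tp_tr / tr_n_ca + tn_tr / tr_n_co) / 2.0
        elif tr_n_ca > 0:
            train_ba[f] = tp_tr / tr_n_ca
        elif tr_n_co > 0:
            train_ba[f] = tn_tr / tr_n_co
        else:
            train_ba[f] = 0.5
        if fold_ca[f] > 0 and fold_co[f] > 0:
            test_ba[f] = (tp_te / fold_ca[f] + tn_te / fold_co[f]) / 2.0
        elif fold_ca[f] > 0:
            test_ba[f] = tp_te / fold_ca[f]
        elif fold_co[f] > 0:
            test_ba[f] = tn_te / fold_co[f]
        else:
            test_ba[f] = 0.5
        cvv_sum += test_ba[f]
    return cvv_sum / n_folds


@njit(cache=True)
def _scan_kernel(
    geno, status, fold_ids, n_folds, policy_mis, fixed_t, pi, pj
):  # pragma: no cover - exercised via wrappers
    """CVV for a batch of pairs; columns of ``geno`` indexed by pi/pj."""
    n = geno.shape[0]
    out = np.empty(pi.shape[0])
    cells = np.empty(n, dtype=np.int64)
    tr = np.empty(n_folds)
    te = np.empty(n_folds)
    for p in range(pi.shape[0]):
        j1 = pi[p]
        j2 = pj[p]
        for i in range(n):
            a = geno[i, j1]
            b = geno[i, j2]
            cells[i] = 3 * a + b if (a >= 0 and b >= 0) else -1
        out[p] = _eval_cells(
            cells, status, fold_ids, n_folds, policy_mis, fixed_t, tr, te
        )
    return out


def _pair_cells(ds: GenotypeDataset, j1: int, j2: int) -> np.ndarray:
    g1 = ds.genotypes[:, j1].astype(np.int64)
    g2 = ds.genotypes[:, j2].astype(np.int64)
    return np.where((g1 >= 0) & (g2 >= 0), 3 * g1 + g2, -1)


def _fixed_t(config: MDRConfig) -> float:
    return -1.0 if config.ratio_threshold is None else float(config.ratio_threshold)


# ---------------------------------------------------------------------------
# public evaluation API
# ---------------------------------------------------------------------------


def evaluate_pair(
    ds: GenotypeDataset,
    pair: tuple[str, str],
    config: MDRConfig | None = None,
    fold_ids: Optional[np.ndarray] = None,
) -> MDRModel:
    """Cross-validate the MDR classifier for one SNP pair.

    For each fold the risk grid is fitted on the other folds and the
    held-out samples are classified (high -> case, low -> control;
    empty-cell / missing-genotype samples per the configured policy).  CVV
    is the mean held-out balanced accuracy.
    """
    config = config or MDRConfig()
    id1, id2 = pair
    j1, j2 = ds.variant_index(id1), ds.variant_index(id2)
    if j1 == j2:
        raise ValueError("pair must consist of two distinct variants")
    status = ds.status_array.astype(np.int64)
    if fold_ids is None:
        fold_ids = make_folds(status, config.n_folds, config.seed)
    cells = _pair_cells(ds, j1, j2)
    train_ba = np.empty(config.n_folds)
    test_ba = np.empty(config.n_folds)
    cvv = float(
        _eval_cells(
            cells,
            status,
            fold_ids.astype(np.int64),
            config.n_folds,
            config.empty_cell_policy == "unknown_misclassified",
            _fixed_t(config),
            train_ba,
            test_ba,
        )
    )
    grids = []
    for f in range(config.n_folds):
        train = fold_ids != f
        ok = train & (cells >= 0)
        ca = np.bincount(cells[ok & (status == 1)], minlength=9).reshape(3, 3)
        co = np.bincount(cells[ok & (status == 0)], minlength=9).reshape(3, 3)
        t_num, t_den = int(ca.sum()), int(co.sum())
        labels = np.empty((3, 3), dtype=np.int8)
        for a in range(3):
            for b in range(3):
                labels[a, b] = _label_cell(
                    int(ca[a, b]), int(co[a, b]), t_num, t_den, _fixed_t(config)
                )
        grids.append(RiskGrid(labels=labels, case_counts=ca, control_counts=co))
    v1, v2 = ds.variants[j1], ds.variants[j2]
    return MDRModel(
        id1=id1,
        id2=id2,
        gene1=v1.gene,
        gene2=v2.gene,
        fold_grids=grids,
        train_ba=train_ba,
        test_ba=test_ba,
        cvv=cvv,
        significant=cvv > config.cvv_threshold,
    )


def all_pairs(variant_ids: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered pairs, each ordered lexicographically within the pair."""
    ids = sorted(variant_ids)
    return [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]


def scan_pairs(
    ds: GenotypeDataset,
    pairs: Optional[Sequence[tuple[str, str]]] = None,
    config: MDRConfig | None = None,
    workers: int = 1,
) -> ScanResult:
    """Exhaustive MDR scan over a pair universe.

    ``pairs`` defaults to all unordered pairs of the dataset's variants
    (restrict to gene-mapped tag SNPs upstream for the screen's standard
    universe).  The scan is a pure map: identical output for any ``workers``
    value.  Pairs are ranked by CVV descending, ties by (id1, id2); detailed
    models are materialised for the top ``config.top_n``.
    """
    config = config or MDRConfig()
    if pairs is None:
        pairs = all_pairs(ds.variant_ids)
    pairs = [tuple(sorted(p)) for p in pairs]
    if len(pairs) == 0:
        raise ValueError("empty pair universe")
    status = ds.status_array.astype(np.int64)
    fold_ids = make_folds(status, config.n_folds, config.seed)
    vindex = {vid: j for j, vid in enumerate(ds.variant_ids)}
    pi = np.array([vindex[a] for a, _ in pairs], dtype=np.int64)
    pj = np.array([vindex[b] for _, b in pairs], dtype=np.int64)
    geno = np.ascontiguousarray(ds.genotypes.astype(np.int64))
    policy_mis = config.empty_cell_policy == "unknown_misclassified"
    ft = _fixed_t(config)

    if workers <= 1 or len(pairs) < 2 * workers:
        cvv = _scan_kernel(
            geno, status, fold_ids, config.n_folds, policy_mis, ft, pi, pj
        )
    else:
        chunks = np.array_split(np.arange(len(pairs)), workers)
        parts = Parallel(n_jobs=workers, prefer="threads")(
            delayed(_scan_kernel)(
                geno, status, fold_ids, config.n_folds, policy_mis, ft, pi[c], pj[c]
            )
            for c in chunks
            if c.size
        )
        cvv = np.concatenate(parts)

    table = pd.DataFrame(
        {"id1": [a for a, _ in pairs], "id2": [b for _, b in pairs], "cvv": cvv}
    )
    table = table.sort_values(
        by=["cvv", "id1", "id2"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    top = table.head(config.top_n)
    models = [
        evaluate_pair(ds, (row.id1, row.id2), config, fold_ids=fold_ids)
        for row in top.itertuples()
    ]
    return ScanResult(models=models, table=table, config=config)


def significance_filter(
    models: Sequence[MDRModel], cvv_threshold: float = 0.5
) -> list[MDRModel]:
    """Models with CVV strictly greater than the threshold."""
    return [m for m in models if m.cvv > cvv_threshold]


# ---------------------------------------------------------------------------
# permutation nulls
# ---------------------------------------------------------------------------


def permutation_null(
    ds: GenotypeDataset,
    pair: tuple[str, str],
    n_perm: int = 1000,
    seed: int = 0,
    config: MDRConfig | None = None,
) -> tuple[float, float, np.ndarray]:
    """Empirical CVV p-value for one FIXED pair by label permutation.

    Phenotype labels are permuted across the whole cohort and the full
    procedure (stratified folds included) is re-run.  Returns
    (observed_cvv, p, null_cvvs) with the add-one estimator
    p = (1 + #{perm >= obs}) / (n_perm + 1).

    This p-value is calibrated for a pair chosen independently of its CVV;
    for the top-ranked pair of a scan use :func:`scan_max_null`, which
    accounts for selection.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    config = config or MDRConfig()
    observed = evaluate_pair(ds, pair, config).cvv
    j1, j2 = ds.variant_index(pair[0]), ds.variant_index(pair[1])
    cells = _pair_cells(ds, j1, j2)
    status = ds.status_array.astype(np.int64)
    rng = np.random.default_rng(seed)
    policy_mis = config.empty_cell_policy == "unknown_misclassified"
    ft = _fixed_t(config)
    tr = np.empty(config.n_folds)
    te = np.empty(config.n_folds)
    null = np.empty(n_perm)
    for t in range(n_perm):
        perm_status = rng.permutation(status)
        folds = make_folds(perm_status, config.n_folds, int(rng.integers(2**31)))
        null[t] = _eval_cells(
            cells, perm_status, folds, config.n_folds, policy_mis, ft, tr, te
        )
    p = (1.0 + int((null >= observed).sum())) / (n_perm + 1.0)
    return float(observed), float(p), null


def scan_max_null(
    ds: GenotypeDataset,
    pairs: Optional[Sequence[tuple[str, str]]] = None,
    config: MDRConfig | None = None,
    n_perm: int = 99,
    seed: int = 0,
) -> np.ndarray:
    """Null distribution of the scan's maximum CVV by label permutation.

    For each permutation the labels are shuffled, folds re-stratified and
    the whole pair universe re-scanned; the max CVV is recorded.  Comparing
    an observed top-ranked CVV against this distribution gives a
    selection-corrected (family-wise) empirical p-value via
    :func:`max_null_pvalue`.
    """
    config = config or MDRConfig()
    if pairs is None:
        pairs = all_pairs(ds.variant_ids)
    pairs = [tuple(sorted(p)) for p in pairs]
    vindex = {vid: j for j, vid in enumerate(ds.variant_ids)}
    pi = np.array([vindex[a] for a, _ in pairs], dtype=np.int64)
    pj = np.array([vindex[b] for _, b in pairs], dtype=np.int64)
    geno = np.ascontiguousarray(ds.genotypes.astype(np.int64))
    status = ds.status_array.astype(np.int64)
    rng = np.random.default_rng(seed)
    policy_mis = config.empty_cell_policy == "unknown_misclassified"
    ft = _fixed_t(config)
    out = np.empty(n_perm)
    for t in range(n_perm):
        perm_status = rng.permutation(status)
        folds = make_folds(perm_status, config.n_folds, int(rng.integers(2**31)))
        cvv = _scan_kernel(
            geno, perm_status, folds, config.n_folds, policy_mis, ft, pi, pj
        )
        out[t] = cvv.max()
    return out


def max_null_pvalue(observed_cvv: float, null_max: np.ndarray) -> float:
    """Add-one empirical p of an observed CVV against a max-CVV null."""
    return (1.0 + int((null_max >= observed_cvv).sum())) / (null_max.size + 1.0)
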