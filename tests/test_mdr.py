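"""MDR engine: folds, risk grids, cross-validation, scanning, permutation."""

import numpy as np
import pytest

from episcreen import (
    GenotypeDataset,
    MDRConfig,
    SampleInfo,
    VariantInfo,
    all_pairs,
    evaluate_pair,
    fit_risk_grid,
    make_folds,
    max_null_pvalue,
    permutation_null,
    scan_pairs,
    significance_filter,
)
from episcreen.mdr import _eval_cells, _pair_cells
from oracles import naive_mdr_cvv


def _ds(geno, statuses):
    geno = np.asarray(geno, dtype=np.int8)
    n, m = geno.shape
    return GenotypeDataset(
        geno,
        [VariantInfo(id=f"v{j:02d}", pos=j + 1, allele_a="A", allele_b="G") for j in range(m)],
        [SampleInfo(id=f"s{i:03d}", status=s) for i, s in enumerate(statuses)],
    )


def _random_instance(rng, n_max=20, n_folds=3):
    """A random micro-instance with missingness, valid for stratified folds."""
    while True:
        n = int(rng.integers(2 * n_folds, n_max + 1))
        status = rng.integers(0, 2, n)
        if status.sum() >= n_folds and (n - status.sum()) >= n_folds:
            break
    g1 = rng.integers(0, 3, n)
    g2 = rng.integers(0, 3, n)
    g1[rng.random(n) < 0.1] = -1
    g2[rng.random(n) < 0.1] = -1
    return g1, g2, status


class TestMakeFolds:
    def test_unbalanced_cohort_counts(self):
        # 49 cases / 109 controls over 10 folds
        status = np.array([1] * 49 + [0] * 109)
        folds = make_folds(status, 10, seed=1)
        case_counts = np.bincount(folds[status == 1], minlength=10)
        ctrl_counts = np.bincount(folds[status == 0], minlength=10)
        assert set(case_counts) <= {4, 5}
        assert set(ctrl_counts) <= {10, 11}

    def test_leave_one_out_partition(self):
        status = np.array([1, 0] * 5)
        folds = make_folds(status, 5, seed=0)
        assert sorted(np.bincount(folds).tolist()) == [2] * 5

    def test_deterministic_under_seed(self):
        status = np.array([1] * 20 + [0] * 30)
        assert np.array_equal(make_folds(status, 10, 7), make_folds(status, 10, 7))
        assert not np.array_equal(make_folds(status, 10, 7), make_folds(status, 10, 8))

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError):
            make_folds(np.array([1, 1, 0, 0]), 3, 0)


class TestFitRiskGrid:
    def test_cell_labelling_rules(self):
        g1 = np.array([0, 0, 0, 0, 1, 1, 2])
        g2 = np.array([0, 0, 0, 0, 0, 0, 0])
        status = np.array([1, 1, 1, 0, 1, 1, 0])
        grid = fit_risk_grid(g1, g2, status, T=1.0)
        assert grid.labels[0, 0] == 1  # 3 cases / 1 control >= 1
        assert grid.labels[1, 0] == 1  # 2 cases / 0 controls -> high
        assert grid.labels[2, 0] == 0  # 0 cases / 1 control
        assert grid.labels[2, 2] == -1  # empty
        assert grid.case_counts[0, 0] == 3 and grid.control_counts[0, 0] == 1

    def test_missing_genotypes_excluded(self):
        g1 = np.array([0, -1, 0])
        g2 = np.array([0, 0, -1])
        grid = fit_risk_grid(g1, g2, np.array([1, 1, 1]), T=1.0)
        assert grid.case_counts.sum() == 1

    def test_relabel_symmetry_of_balanced_accuracy(self):
        # swapping case<->control and inverting risk labels swaps
        # sensitivity and specificity, leaving balanced accuracy unchanged
        rng = np.random.default_rng(3)
        g1, g2 = rng.integers(0, 3, 60), rng.integers(0, 3, 60)
        status = rng.integers(0, 2, 60)
        grid = fit_risk_grid(g1, g2, status, T=1.0)
        occupied = grid.labels[g1, g2] >= 0
        g1, g2, status = g1[occupied], g2[occupied], status[occupied]
        pred = grid.labels[g1, g2] == 1
        sens = pred[status == 1].mean()
        spec = (~pred)[status == 0].mean()
        inv_pred = ~pred
        inv_status = 1 - status
        sens_inv = inv_pred[inv_status == 1].mean()
        spec_inv = (~inv_pred)[inv_status == 0].mean()
        assert (sens + spec) / 2 == pytest.approx((sens_inv + spec_inv) / 2)


class TestEvaluatePair:
    def test_perfect_separation_scores_one(self):
        rng = np.random.default_rng(0)
        status = np.array([1] * 20 + [0] * 20)
        g1 = status * 2
        g2 = rng.integers(0, 3, 40)
        ds = _ds(np.column_stack([g1, g2]), ["case" if s else "control" for s in status])
        model = evaluate_pair(ds, ("v00", "v01"), MDRConfig(seed=1))
        assert model.cvv == pytest.approx(1.0)
        assert model.significant

    def test_matches_naive_oracle_on_micro_instances(self):
        rng = np.random.default_rng(17)
        n_folds = 3
        for rep in range(20):
            g1, g2, status = _random_instance(rng)
            ds = _ds(
                np.column_stack([g1, g2]),
                ["case" if s else "control" for s in status],
            )
            for policy in ("low_risk", "unknown_misclassified"):
                cfg = MDRConfig(n_folds=n_folds, seed=rep, empty_cell_policy=policy)
                folds = make_folds(status, n_folds, rep)
                want = naive_mdr_cvv(
                    list(g1), list(g2), list(status), list(folds), n_folds,
                    policy=policy,
                )
                got = evaluate_pair(ds, ("v00", "v01"), cfg).cvv
                assert got == want, f"rep={rep} policy={policy}"

    def test_fixed_threshold_matches_oracle(self):
        rng = np.random.default_rng(23)
        for rep in range(10):
            g1, g2, status = _random_instance(rng)
            ds = _ds(np.column_stack([g1, g2]),
                     ["case" if s else "control" for s in status])
            folds = make_folds(status, 3, rep)
            cfg = MDRConfig(n_folds=3, seed=rep, ratio_threshold=1.0)
            want = naive_mdr_cvv(list(g1), list(g2), list(status), list(folds),
                                 3, T=1.0)
            assert evaluate_pair(ds, ("v00", "v01"), cfg).cvv == want

    def test_null_mean_cvv_is_half(self):
        # permuted phenotypes: E[CVV] = 0.5 exactly under the null
        rng = np.random.default_rng(5)
        n = 100
        g1, g2 = rng.integers(0, 3, n), rng.integers(0, 3, n)
        cells = np.where((g1 >= 0) & (g2 >= 0), 3 * g1 + g2, -1).astype(np.int64)
        base = np.array([1] * 30 + [0] * 70)
        vals = []
        tr, te = np.empty(10), np.empty(10)
        for rep in range(300):
            status = rng.permutation(base).astype(np.int64)
            folds = make_folds(status, 10, rep)
            vals.append(
                _eval_cells(cells, status, folds, 10, False, -1.0, tr, te)
            )
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 0.5) < 3 * se

    def test_identical_pair_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            evaluate_pair(tiny_dataset, ("rs1", "rs1"))

    def test_cvv_in_unit_interval_and_grids_complete(self, planted_cohort):
        ds, _ = planted_cohort
        m = evaluate_pair(ds, ("snp00000", "snp00100"), MDRConfig(seed=3))
        assert 0.0 <= m.cvv <= 1.0
        assert len(m.fold_grids) == 10
        for grid in m.fold_grids:
            assert set(np.unique(grid.labels)) <= {-1, 0, 1}


class TestScanPairs:
    def test_single_pair_scan_equals_evaluate_pair(self, planted_cohort):
        ds, _ = planted_cohort
        cfg = MDRConfig(seed=11)
        scan = scan_pairs(ds, pairs=[("snp00000", "snp00100")], config=cfg)
        direct = evaluate_pair(ds, ("snp00000", "snp00100"), cfg)
        assert scan.table.cvv[0] == direct.cvv
        assert scan.models[0].cvv == direct.cvv

    def test_worker_count_invariance(self, null_cohort):
        ds, _ = null_cohort
        sub = ds.subset(variant_idx=range(30))
        cfg = MDRConfig(seed=2)
        t1 = scan_pairs(sub, config=cfg, workers=1).table
        t8 = scan_pairs(sub, config=cfg, workers=8).table
        assert t1.equals(t8)

    def test_planted_pair_ranks_first(self, planted_cohort):
        ds, _ = planted_cohort
        scan = scan_pairs(ds, config=MDRConfig(seed=9))
        assert {scan.table.id1[0], scan.table.id2[0]} == {"snp00000", "snp00100"}

    def test_ranking_ties_broken_lexicographically(self):
        status = ["case"] * 10 + ["control"] * 10
        geno = np.zeros((20, 3), dtype=np.int8)  # all pairs equivalent
        ds = _ds(geno, status)
        scan = scan_pairs(ds, config=MDRConfig(n_folds=2, seed=0))
        pairs = list(zip(scan.table.id1, scan.table.id2))
        assert pairs == sorted(pairs)

    def test_empty_universe_raises(self, tiny_dataset):
        with pytest.raises(ValueError):
            scan_pairs(tiny_dataset, pairs=[])


class TestSignificanceFilter:
    def test_strict_threshold_boundary(self):
        # lightweight stand-ins: the filter only reads .cvv
        class M:
            def __init__(self, cvv):
                self.cvv = cvv

        models = [M(0.709), M(0.548), M(0.500), M(0.499)]
        kept = significance_filter(models, 0.5)
        assert [m.cvv for m in kept] == [0.709, 0.548]


class TestPermutationNull:
    def test_perfect_separation_minimum_p(self):
        status = np.array([1] * 15 + [0] * 15)
        rng = np.random.default_rng(1)
        geno = np.column_stack([status * 2, rng.integers(0, 3, 30)])
        ds = _ds(geno, ["case" if s else "control" for s in status])
        obs, p, null = permutation_null(
            ds, ("v00", "v01"), n_perm=199, seed=3, config=MDRConfig(n_folds=5, seed=3)
        )
        assert obs == pytest.approx(1.0)
        assert p == pytest.approx(1 / 200)

    def test_add_one_estimator_form(self):
        null = np.array([0.4, 0.5, 0.62, 0.7])
        assert max_null_pvalue(0.65, null) == pytest.approx(2 / 5)
        assert max_null_pvalue(0.99, null) == pytest.approx(1 / 5)

    def test_null_pair_p_uniform(self, null_cohort):
        ds, _ = null_cohort
        ps = []
        for rep in range(30):
            _, p, _ = permutation_null(
                ds,
                (f"snp{2*rep:05d}", f"snp{2*rep+1:05d}"),
                n_perm=120,
                seed=rep,
                config=MDRConfig(seed=rep),
            )
            ps.append(p)
        from scipy import stats as sps

        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_n_perm_floor(self, tiny_dataset):
        with pytest.raises(ValueError):
            permutation_null(tiny_dataset, ("rs0", "rs1"), n_perm=10)

    def test_selection_corrected_top_pair_p_uniform(self):
        """The max-CVV permutation p of a null scan's best pair is uniform.

        30 replicate null cohorts, each scanned exhaustively; the top-ranked
        pair's p against the rescanned max-CVV null should behave like a
        U(0,1) draw (the whole point of correcting for selecting the max).
        """
        from scipy import stats as sps

        from episcreen import (
            SimConfig,
            make_penetrance_model,
            scan_max_null,
            scan_pairs,
            simulate_cohort,
        )

        null_model = make_penetrance_model("null", 0.3, maf1=0.3, maf2=0.3)
        ps = []
        for seed in range(300, 330):
            cfg = SimConfig(n_cases=65, n_controls=195, n_snps=30,
                            planted=[(0, 15, null_model)], seed=seed)
            ds, _ = simulate_cohort(cfg)
            mdr_cfg = MDRConfig(seed=seed)
            scan = scan_pairs(ds, config=mdr_cfg)
            null_max = scan_max_null(ds, config=mdr_cfg, n_perm=99, seed=seed + 7)
            ps.append(max_null_pvalue(scan.table.cvv[0], null_max))
        assert sps.kstest(ps, "uniform").pvalue > 0.01
        # nominal pass probability at 0.05 is 0.04; allow binomial noise
        assert sum(p < 0.05 for p in ps) <= 4
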