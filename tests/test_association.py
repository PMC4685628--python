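"""Single-SNP association: ORs, allelic chi-square, logistic fits, BH, lambda."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from episcreen import (
    SimConfig,
    allele_table,
    allelic_test,
    associate_all,
    bh_adjust,
    logistic_assoc,
    odds_ratio,
    odds_ratio_counts,
    qq_lambda,
    simulate_cohort,
)

# Published case/control minor-allele frequencies for SNPs in significant
# thyroid-carcinoma interactions, with the odds ratios printed alongside them.
PUBLISHED_OR_ROWS = [
    ("rs4758915", 0.03704, 0.02586, 1.449),
    ("rs10402530", 0.1944, 0.1897, 1.031),
    ("rs7835921", 0.4519, 0.5086, 0.7966),
    ("rs1287079", 0.3019, 0.3664, 0.7479),
    ("rs2235544", 0.4667, 0.5043, 0.86),
    ("rs16876356", 0.1167, 0.2308, 0.4403),
    ("rs17716031", 0.1034, 0.1336, 0.7481),
    ("rs10775207", 0.0167, 0.0087, 1.932),
]


class TestOddsRatio:
    @pytest.mark.parametrize("snp,f_ca,f_co,printed", PUBLISHED_OR_ROWS)
    def test_published_frequency_pairs(self, snp, f_ca, f_co, printed):
        # frequencies are printed to 4 decimals, so the last digit of the
        # printed OR can be off by ~0.2% relative
        assert odds_ratio(f_ca, f_co) == pytest.approx(printed, rel=2e-3)

    def test_equal_frequencies_give_unity(self):
        for p in (0.01, 0.3, 0.73):
            assert odds_ratio(p, p) == pytest.approx(1.0)

    def test_frequency_and_count_forms_agree(self):
        counts = (30, 70, 20, 80)
        f_ca, f_co = 0.3, 0.2
        or_counts, _ = odds_ratio_counts(counts)
        assert or_counts == pytest.approx(odds_ratio(f_ca, f_co))

    def test_allele_swap_inverts_or(self):
        a, b, c, d = 30, 70, 20, 80
        or1, _ = odds_ratio_counts((a, b, c, d))
        or2, _ = odds_ratio_counts((b, a, d, c))
        assert or1 * or2 == pytest.approx(1.0)

    def test_woolf_ci_contains_or(self):
        or_, (lo, hi) = odds_ratio_counts((30, 70, 20, 80))
        assert lo < or_ < hi

    def test_zero_cell_requires_continuity(self):
        with pytest.raises(ValueError, match="continuity"):
            odds_ratio_counts((0, 70, 20, 80))
        or_, (lo, hi) = odds_ratio_counts((0, 70, 20, 80), continuity=True)
        assert 0 < lo < or_ < hi

    def test_boundary_frequency_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio(0.0, 0.5)


class TestAlleleTable:
    def test_direct_count(self, tiny_dataset):
        # cases s0..s2 at rs1: codes 0,1,2 -> 3 minor of 6
        a, b, c, d = allele_table(tiny_dataset, "rs0")
        assert (a, b) == (3, 3)
        assert a / (a + b) == pytest.approx(0.5)

    def test_all_missing_group_errors(self, tiny_dataset):
        ds = tiny_dataset.copy()
        ds.genotypes[3:, 3] = -1  # controls all missing at rs3
        with pytest.raises(ValueError, match="controls"):
            allele_table(ds, "rs3")


class TestAllelicTest:
    def test_identical_groups_null(self):
        stat, p = allelic_test((10, 90, 10, 90))
        assert stat == 0.0 and p == 1.0

    def test_hand_computed_chi_square(self):
        # O-E table gives sum (O-E)^2/E = 12.5 exactly
        stat, p = allelic_test((30, 70, 10, 90))
        assert stat == pytest.approx(12.5)
        assert p == pytest.approx(sps.chi2.sf(12.5, 1), rel=1e-6)
        assert p == pytest.approx(4.07e-4, rel=5e-3)

    def test_agrees_with_independent_routine(self):
        for tab in [(30, 70, 10, 90), (5, 15, 8, 12), (100, 50, 80, 70)]:
            stat, p = allelic_test(tab)
            ref = sps.chi2_contingency(
                np.array(tab).reshape(2, 2), correction=False
            )
            assert stat == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_transpose_invariance(self):
        a, b, c, d = 12, 34, 21, 9
        assert allelic_test((a, b, c, d))[0] == pytest.approx(
            allelic_test((a, c, b, d))[0]
        )

    def test_zero_margin_convention(self):
        assert allelic_test((0, 10, 0, 20)) == (0.0, 1.0)

    def test_type_one_error_calibrated(self):
        # alpha=0.05 rejection rate within [0.04, 0.06]: 260 samples, MAF 0.3
        rng = np.random.default_rng(99)
        n_rep, f = 10_000, 0.3
        a = rng.binomial(130, f, n_rep)  # case alleles (65 cases)
        c = rng.binomial(390, f, n_rep)  # control alleles (195 controls)
        rej = 0
        for i in range(n_rep):
            _, p = allelic_test((a[i], 130 - a[i], c[i], 390 - c[i]))
            rej += p < 0.05
        assert 0.04 <= rej / n_rep <= 0.06


class TestLogisticAssoc:
    def test_constant_genotype_flagged(self, tiny_dataset):
        ds = tiny_dataset.copy()
        ds.genotypes[:, 1] = 1
        out = logistic_assoc(ds, ["rs1"], covariates=())
        assert not out.ok[0] and np.isnan(out.p[0])

    def test_concordant_with_allelic_test_at_scale(self):
        cfg = SimConfig(n_cases=250, n_controls=250, n_snps=60, block_size=1,
                        missing_rate=0.0, planted=[], background_prevalence=0.5,
                        seed=31)
        ds, _ = simulate_cohort(cfg)
        out = logistic_assoc(ds, covariates=())
        p_allelic = [allelic_test(allele_table(ds, v))[1] for v in ds.variant_ids]
        ok = out.ok.to_numpy()
        rho = sps.spearmanr(out.p[ok], np.array(p_allelic)[ok]).statistic
        assert rho > 0.95

    def test_null_pvalues_uniform(self):
        cfg = SimConfig(n_cases=150, n_controls=150, n_snps=200, block_size=1,
                        missing_rate=0.0, planted=[], background_prevalence=0.5,
                        seed=32)
        ds, _ = simulate_cohort(cfg)
        out = logistic_assoc(ds)
        ps = out.p[out.ok].to_numpy()
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestBhAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.57])[0] == pytest.approx(0.57)

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    @given(
        st.lists(
            st.floats(min_value=1e-6, max_value=1.0, exclude_min=False),
            min_size=1,
            max_size=30,
        )
    )
    @settings(deadline=None, max_examples=100)
    def test_adjusted_dominates_and_is_permutation_equivariant(self, ps):
        adj = bh_adjust(ps)
        assert (adj >= np.asarray(ps) - 1e-15).all()
        assert (adj <= 1.0 + 1e-15).all()
        perm = np.random.default_rng(0).permutation(len(ps))
        adj_perm = bh_adjust([ps[i] for i in perm])
        np.testing.assert_allclose(adj_perm, adj[perm], rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])


class TestQqLambda:
    def test_uniform_grid_gives_unity(self):
        m = 1001
        p = (np.arange(1, m + 1) - 0.5) / m
        assert qq_lambda(p).lambda_gc == pytest.approx(1.0, abs=1e-6)

    def test_deflation_monotone(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=5000)
        lam1 = qq_lambda(p).lambda_gc
        lam2 = qq_lambda(np.clip(p * 0.1, 1e-300, 1)).lambda_gc
        assert lam2 > lam1

    def test_null_simulation_lambda_near_one(self):
        rng = np.random.default_rng(2)
        p = sps.chi2.sf(rng.chisquare(1, size=20_000), 1)
        lam = qq_lambda(p).lambda_gc
        assert 0.9 < lam < 1.1

    def test_requires_ten_values(self):
        with pytest.raises(ValueError):
            qq_lambda([0.5] * 9)


class TestAssociateAll:
    def test_bh_applied_and_or_orientation(self, planted_cohort):
        ds, _ = planted_cohort
        res = associate_all(ds, ds.variant_ids[:30])
        assert len(res) == 30
        for r in res:
            assert r.p_adjusted >= r.p_nominal - 1e-15
            assert r.ci95[0] <= r.odds_ratio <= r.ci95[1]
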