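from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rvassoc import burden
from rvassoc.core import MISSING, DataError

from conftest import make_cohort


class TestClassifyMaf:
    @pytest.mark.parametrize(
        "maf,expected",
        [
            (0.009, "rare"),
            (0.0, "rare"),
            (0.01, "low-frequency"),  # boundary inclusive on the low-freq side
            (0.049, "low-frequency"),
            (0.05, "common"),
            (0.5, "common"),
        ],
    )
    def test_boundaries(self, maf, expected):
        assert burden.classify_maf(maf) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            burden.classify_maf(0.6)
        with pytest.raises(DataError):
            burden.classify_maf(-0.01)

    @given(st.floats(min_value=0.0, max_value=0.5, allow_nan=False))
    def test_partition(self, maf):
        assert burden.classify_maf(maf) in {"rare", "low-frequency", "common"}


# toy matrix: 2 variants x 4 samples (cases first two)
TOY = np.array([[1, 0, 0, 2], [0, 1, 1, 0]], dtype=np.int8)
TOY_CASE = np.array([True, True, False, False])


class TestStatistics:
    def test_burden_no_minor_alleles(self):
        assert burden.burden_stat(np.zeros((3, 6), dtype=np.int8), np.arange(6) < 3) == 0

    def test_burden_hand_count(self):
        # cases carry 1 (v1) + 1 (v2) = 2 minor alleles
        assert burden.burden_stat(TOY, TOY_CASE) == 2.0

    def test_burden_all_in_controls(self):
        d = np.array([[0, 0, 2, 1]], dtype=np.int8)
        assert burden.burden_stat(d, TOY_CASE) == 0.0

    def test_burden_missing_counts_zero(self):
        d = np.array([[MISSING, 2, 0, 0]], dtype=np.int8)
        assert burden.burden_stat(d, TOY_CASE) == 2.0

    def test_frqwgt_hand_arithmetic(self):
        # v1: ctrl count 2 of 2 ctrl samples -> q = 3/6, w1 = 1/sqrt(2*.5*.5)
        # v2: ctrl count 1 -> q = 2/6, w2 = 1/sqrt(2*(1/3)*(2/3))
        w1 = 1 / np.sqrt(2 * 0.5 * 0.5)
        w2 = 1 / np.sqrt(2 * (2 / 6) * (4 / 6))
        expected = w1 * 1 + w2 * 1  # case minor alleles per variant
        assert burden.frqwgt_stat(TOY, TOY_CASE) == pytest.approx(expected)

    def test_frqwgt_constant_weights_proportional_to_burden(self, rng):
        d = rng.integers(0, 2, size=(4, 40)).astype(np.int8)
        case = np.arange(40) < 20
        # same control counts per variant -> equal weights
        d[:, ~case] = d[0, ~case]
        w = 1 / np.sqrt(
            20
            * ((d[0, ~case].sum() + 1) / 42)
            * (1 - (d[0, ~case].sum() + 1) / 42)
        )
        assert burden.frqwgt_stat(d, case) == pytest.approx(
            w * burden.burden_stat(d, case)
        )

    def test_frqwgt_rare_variants_weigh_more(self):
        d = np.array(
            [[1, 0, 0, 0, 0, 0], [1, 0, 1, 1, 1, 1]], dtype=np.int8
        )
        case = np.arange(6) < 2
        w = burden._frqwgt_weights(d, case)
        assert w[0] > w[1]

    def test_uniq_no_case_unique(self):
        d = np.array([[1, 0, 1, 0], [0, 1, 0, 1]], dtype=np.int8)
        assert burden.uniq_stat(d, TOY_CASE) == 0.0

    def test_uniq_four_case_only_singletons(self):
        d = np.zeros((4, 8), dtype=np.int8)
        for j in range(4):
            d[j, j % 4] = 1  # carriers are all among the 4 cases
        assert burden.uniq_stat(d, np.arange(8) < 4) == 4.0

    def test_uniq_hand_count(self):
        # v1 case-unique with 3 case alleles; v2 seen in a control
        d = np.array([[2, 1, 0, 0], [1, 0, 1, 0]], dtype=np.int8)
        assert burden.uniq_stat(d, TOY_CASE) == 3.0

    def test_vt_single_threshold_equals_standardized_burden(self):
        mafs = np.array([0.004, 0.004])
        z = burden.vt_stat(TOY, mafs, TOY_CASE)
        y = TOY.sum(axis=0).astype(float)
        s = y[TOY_CASE].sum()
        mu = 2 * y.mean()
        var = 2 * (4 - 2) / 3 * y.var()
        assert z == pytest.approx((s - mu) / np.sqrt(var))

    def test_vt_two_thresholds_enumeration(self):
        d = np.array([[1, 1, 0, 0, 0, 0], [0, 1, 1, 0, 1, 0]], dtype=np.int8)
        mafs = np.array([0.001, 0.008])
        case = np.arange(6) < 3

        def z_for(sub):
            y = d[sub].sum(axis=0).astype(float)
            s = y[case].sum()
            mu = 3 * y.mean()
            var = 3 * (6 - 3) / 5 * y.var()
            return (s - mu) / np.sqrt(var) if var > 0 else 0.0

        expected = max(z_for([0]), z_for([0, 1]))
        assert burden.vt_stat(d, mafs, case) == pytest.approx(expected)

    def test_vt_ignores_higher_maf_only_thresholds(self):
        d = np.vstack([TOY, np.ones((1, 4), dtype=np.int8)])
        mafs = np.array([0.004, 0.004, 0.3])
        base = burden.vt_stat(TOY, np.array([0.004, 0.004]), TOY_CASE)
        # the extra threshold adds a candidate but the restricted max includes base
        assert burden.vt_stat(d, mafs, TOY_CASE) >= base

    @pytest.mark.parametrize("test", burden.TESTS)
    def test_order_invariance(self, test, rng):
        d = rng.integers(0, 3, size=(5, 30)).astype(np.int8)
        mafs = rng.uniform(0.001, 0.01, 5)
        case = np.arange(30) < 12
        gt = burden.make_test(test, d, mafs)
        obs = gt.observed(case)
        sperm = rng.permutation(30)
        vperm = rng.permutation(5)
        gt2 = burden.make_test(test, d[vperm][:, sperm], mafs[vperm])
        assert gt2.observed(case[sperm]) == pytest.approx(obs)

    @pytest.mark.parametrize("test", ["burden", "frqwgt", "uniq"])
    def test_case_only_allele_monotone(self, test, rng):
        d = rng.integers(0, 2, size=(4, 20)).astype(np.int8)
        mafs = np.full(4, 0.005)
        case = np.arange(20) < 10
        before = burden.make_test(test, d, mafs).observed(case)
        extra = np.zeros((1, 20), dtype=np.int8)
        extra[0, 0] = 1  # new case-only minor allele
        d2 = np.vstack([d, extra])
        after = burden.make_test(test, d2, np.full(5, 0.005)).observed(case)
        assert after >= before

    @pytest.mark.parametrize("test", burden.TESTS)
    def test_batch_matches_scalar(self, test, rng):
        d = rng.integers(0, 3, size=(6, 24)).astype(np.int8)
        d[rng.random(d.shape) < 0.05] = MISSING
        mafs = rng.uniform(0.001, 0.04, 6)
        gt = burden.make_test(test, d, mafs)
        scalar_fns = {
            "burden": lambda m: burden.burden_stat(d, m),
            "frqwgt": lambda m: burden.frqwgt_stat(d, m),
            "vt": lambda m: burden.vt_stat(d, mafs, m),
            "uniq": lambda m: burden.uniq_stat(d, m),
        }
        masks = np.zeros((10, 24), dtype=bool)
        for i in range(10):
            masks[i, rng.permutation(24)[:11]] = True
        batch = gt.batch(masks)
        for i in range(10):
            assert batch[i] == pytest.approx(scalar_fns[test](masks[i]))


class TestAdaptivePermutation:
    def test_early_stop_on_null(self, rng):
        d = rng.integers(0, 2, size=(5, 40)).astype(np.int8)
        gt = burden.make_test("burden", d, np.full(5, 0.005))
        case = np.arange(40) < 20
        p, b = burden.adaptive_permutation(gt, case, r_stop=10, b_max=100_000,
                                           seed=1, batch_size=50)
        assert b < 5_000
        assert 0.05 < p <= 1.0

    def test_floor_when_never_exceeded(self):
        d = np.zeros((1, 6), dtype=np.int8)
        d[0, :3] = 2

        class NeverExceeded(burden.GeneTest):
            calls = 0

            def batch(self, masks):
                # observed call comes first; later (permutation) calls lose
                NeverExceeded.calls += 1
                value = 1e9 if NeverExceeded.calls == 1 else -1e9
                return np.full(masks.shape[0], value)

        gt = NeverExceeded.from_dosages("x", d, np.full(1, 0.005))
        case = np.arange(6) < 3
        p, b = burden.adaptive_permutation(gt, case, r_stop=10, b_max=500, seed=0)
        assert b == 500
        assert p == pytest.approx(1 / 501)

    def test_matches_exhaustive_enumeration(self, rng):
        """n=6 cohort: adaptive p ~ exact enumeration over all C(6,3) splits."""
        d = np.array(
            [[1, 2, 0, 0, 1, 0], [1, 0, 0, 1, 0, 0], [2, 1, 1, 0, 0, 0]],
            dtype=np.int8,
        )
        mafs = np.full(3, 0.005)
        case = np.array([True, True, True, False, False, False])
        for test in burden.TESTS:
            gt = burden.make_test(test, d, mafs)
            obs = gt.observed(case)
            stats = []
            for combo in combinations(range(6), 3):
                m = np.zeros(6, bool)
                m[list(combo)] = True
                stats.append(gt.observed(m))
            exact = np.mean([s >= obs - 1e-12 for s in stats])
            p, b = burden.adaptive_permutation(
                gt, case, r_stop=50, b_max=4000, seed=7
            )
            # Monte-Carlo tolerance: 4 sigma of the permutation estimate
            se = np.sqrt(exact * (1 - exact) / b) if 0 < exact < 1 else 0.01
            assert abs(p - exact) <= 4 * se + 2 / b

    def test_adaptive_equals_fixed_b_on_shared_seed(self, rng):
        d = rng.integers(0, 2, size=(4, 20)).astype(np.int8)
        gt = burden.make_test("burden", d, np.full(4, 0.005))
        case = np.arange(20) < 10
        p1, b1 = burden.adaptive_permutation(
            gt, case, r_stop=2000, b_max=2000, seed=5
        )
        p2, b2 = burden.adaptive_permutation(
            gt, case, r_stop=2000, b_max=2000, seed=5
        )
        assert b1 == b2 == 2000
        assert p1 == p2

    def test_invalid_parameters(self):
        gt = burden.make_test("burden", TOY, np.full(2, 0.005))
        with pytest.raises(DataError):
            burden.adaptive_permutation(gt, TOY_CASE, r_stop=0)
        with pytest.raises(DataError):
            burden.adaptive_permutation(gt, TOY_CASE, r_stop=10, b_max=5)

    def test_power_ordering_uniq_vs_burden(self, rng):
        """Case-unique enrichment: UNIQ beats BURDEN more often than not."""
        wins = losses = 0
        n = 60
        case = np.arange(n) < 30
        for rep in range(40):
            d = np.zeros((10, n), dtype=np.int8)
            # noise: variants carried by several samples of both groups,
            # so they are not group-unique and only dilute BURDEN
            for j in range(6):
                d[j, rng.permutation(n)[:5]] = 1
            # signal: case-unique singletons
            for j in range(6, 10):
                d[j, rng.integers(0, 30)] = 1
            mafs = np.full(10, 0.005)
            pu, _ = burden.adaptive_permutation(
                burden.make_test("uniq", d, mafs), case, r_stop=20, b_max=1000,
                seed=rep,
            )
            pb, _ = burden.adaptive_permutation(
                burden.make_test("burden", d, mafs), case, r_stop=20, b_max=1000,
                seed=1000 + rep,
            )
            if pu < pb:
                wins += 1
            elif pu > pb:
                losses += 1
        assert wins > losses


class TestCarrierFisher:
    def test_brwd1_reconstruction(self):
        fc, fx, orr, p, flagged = burden.carrier_table_stats(55, 702, 29, 680)
        assert round(fc, 2) == 7.27 and round(fx, 2) == 4.09
        assert round(orr, 2) == 1.84
        assert round(p, 2) == 0.01
        assert not flagged

    def test_usp26_reconstruction(self):
        fc, fx, orr, p, flagged = burden.carrier_table_stats(9, 748, 2, 707)
        assert round(fc, 2) == 1.19 and round(fx, 2) == 0.28
        assert round(orr, 2) == 4.25
        assert round(p, 2) == 0.07

    def test_null_table(self):
        fc, fx, orr, p, flagged = burden.carrier_table_stats(10, 90, 10, 90)
        assert orr == 1.0 and p == pytest.approx(1.0)

    def test_zero_cell_flagged_with_continuity(self):
        fc, fx, orr, p, flagged = burden.carrier_table_stats(5, 95, 0, 100)
        assert flagged
        assert orr == pytest.approx((5.5 * 100.5) / (95.5 * 0.5))

    def test_gene_carrier_from_dosages(self):
        d = np.array([[1, 0, 0, 0], [2, 0, 1, 0]], dtype=np.int8)
        fc, fx, orr, p, flagged = burden.gene_carrier_fisher(d, TOY_CASE)
        assert fc == 50.0 and fx == 50.0  # 1 carrier per group


class TestReconstructCount:
    @pytest.mark.parametrize(
        "pct,n,dp,expected",
        [
            (7.27, 757, 2, 55),
            (4.09, 709, 2, 29),
            (22.5, 757, 1, 170),
            (13.7, 709, 1, 97),
            (0.0, 100, 2, 0),
        ],
    )
    def test_unique_inversion(self, pct, n, dp, expected):
        assert burden.reconstruct_count(pct, n, dp) == expected

    def test_ambiguous_rejected(self):
        with pytest.raises(DataError):
            burden.reconstruct_count(50.0, 1000, 0)  # 495..504 all round to 50%


class TestRunGeneTests:
    def test_skips_genes_without_qualifying_variants(self, rng):
        from conftest import make_matrix

        d = rng.integers(0, 2, size=(4, 20)).astype(np.int8)
        gm = make_matrix(
            d,
            genes=["G1", "G1", "G2", "G2"],
            vclass=["non-silent", "non-silent", "silent", "silent"],
            mafs=[0.005, 0.006, 0.004, 0.003],
        )
        cohort = make_cohort(10, 10)
        res = burden.run_gene_tests(gm, cohort, b_max=200, seed=0)
        assert [r.gene for r in res] == ["G1"]
        assert set(res[0].p_values) == set(burden.TESTS)
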