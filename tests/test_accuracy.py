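"""Unit and property tests of the paired accuracy statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ngtube_dta import (
    PatientDataset,
    PatientRecord,
    ReferenceMethod,
    TubeLocation,
    average_readers,
    classify_gastric,
    cohen_kappa,
    inter_rater_kappa,
    lung_specificity,
    paired_comparison,
    paired_t_test,
    proportion_ci,
    qc_batch_release,
    sample_size_two_proportions,
    sensitivity_table,
)


def _dataset(std, novel, granularity=0.5):
    """Paired gastric dataset from two equal-length reading lists."""
    recs = tuple(
        PatientRecord(
            patient_id=f"p{i}",
            site_id="site01",
            true_location=TubeLocation.GASTRIC,
            std_r1=s,
            std_r2=s,
            novel_r1=v,
            novel_r2=v,
        )
        for i, (s, v) in enumerate(zip(std, novel))
    )
    return PatientDataset(recs, granularity=granularity)


class TestAverageReaders:
    @pytest.mark.parametrize(
        "r1,r2,expected",
        [
            (5.0, 5.0, 5.0),
            (4.0, 5.0, 4.5),
            (5.5, 5.6, 5.6),  # 5.55 rounds half-up in decimal, not binary
            (4.0, 4.5, 4.3),  # 4.25 -> 4.3
            (None, 6.0, 6.0),
            (6.0, None, 6.0),
        ],
    )
    def test_examples(self, r1, r2, expected):
        assert average_readers(r1, r2) == expected

    def test_both_missing_is_an_error(self):
        with pytest.raises(ValueError):
            average_readers(None, None)


class TestClassify:
    def test_boundary_is_inclusive(self):
        assert classify_gastric(5.5, 5.5)
        assert not classify_gastric(5.6, 5.5)
        assert classify_gastric(1.0, 4.0)

    def test_cutoff_domain(self):
        with pytest.raises(ValueError):
            classify_gastric(5.0, 0.0)


class TestProportionCI:
    def test_published_primary_sensitivity(self):
        est = proportion_ci(185, 376)
        assert round(est.point, 3) == 0.492
        assert round(est.ci_low, 3) == 0.441
        assert round(est.ci_high, 3) == 0.543

    def test_degenerate_zero_numerator(self):
        est = proportion_ci(0, 10)
        assert (est.point, est.ci_low, est.ci_high) == (0.0, 0.0, 0.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            proportion_ci(1, 0)

    def test_matches_statsmodels_normal_interval(self):
        from statsmodels.stats.proportion import proportion_confint

        for k, n in [(1, 10), (5, 10), (185, 376), (264, 376), (99, 100)]:
            lo, hi = proportion_confint(k, n, alpha=0.05, method="normal")
            est = proportion_ci(k, n)
            assert est.ci_low == pytest.approx(max(0.0, lo), abs=1e-12)
            assert est.ci_high == pytest.approx(min(1.0, hi), abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=0, max_value=500),
        st.integers(min_value=1, max_value=500),
        st.sampled_from([0.8, 0.9, 0.95, 0.99]),
    )
    def test_interval_invariants(self, k, n, level):
        k = min(k, n)
        est = proportion_ci(k, n, level)
        assert 0.0 <= est.ci_low <= est.point <= est.ci_high <= 1.0


class TestSensitivityTable:
    def test_empty_cutoff_list_gives_empty_table(self, fixture_dataset):
        assert sensitivity_table(fixture_dataset, cutoffs=()).rows == ()

    def test_all_acidic_readings_give_full_sensitivity(self):
        ds = _dataset([1.0] * 5, [1.0] * 5)
        for row in sensitivity_table(ds).rows:
            assert row.standard.point == 1.0
            assert row.novel.point == 1.0

    def test_sensitivity_nondecreasing_in_cutoff(self, small_cohort, fixture_dataset):
        for ds in (small_cohort, fixture_dataset):
            tab = sensitivity_table(ds, cutoffs=(4.0, 4.5, 5.0, 5.5, 6.0, 7.0))
            for a, b in zip(tab.rows, tab.rows[1:]):
                assert a.standard.point <= b.standard.point
                assert a.novel.point <= b.novel.point

    def test_no_gastric_records_is_an_error(self):
        lung_only = PatientDataset(
            (
                PatientRecord(
                    patient_id="l1",
                    site_id="s",
                    true_location=TubeLocation.LUNG,
                    novel_r1=7.0,
                    novel_r2=7.0,
                    reference_method=ReferenceMethod.CAPNOGRAPHY,
                ),
            )
        )
        with pytest.raises(ValueError, match="gastric"):
            sensitivity_table(lung_only)


class TestLungSpecificity:
    def test_published_values(self, fixture_dataset):
        est = lung_specificity(fixture_dataset, 5.5)
        assert est.numerator == 34 and est.denominator == 38
        assert round(est.point, 3) == 0.895
        assert round(est.ci_low, 3) == 0.796
        assert round(est.ci_high, 3) == 0.994

        assert lung_specificity(fixture_dataset, 5.0).point == 1.0
        est6 = lung_specificity(fixture_dataset, 6.0)
        assert est6.numerator == 30
        assert round(est6.point, 3) == 0.789
        assert round(est6.ci_low, 3) == 0.658
        assert round(est6.ci_high, 3) == 0.921

    def test_no_lung_records_is_an_error(self):
        ds = _dataset([4.0], [4.0])
        with pytest.raises(ValueError, match="lung"):
            lung_specificity(ds, 5.5)


class TestPairedComparison:
    def test_difference_identity_on_fixture(self, fixture_dataset):
        cmp = paired_comparison(fixture_dataset, 5.5)
        assert cmp.difference == pytest.approx((264 - 185) / 376)
        assert cmp.both_pos + cmp.std_only + cmp.novel_only + cmp.both_neg == cmp.n

    def test_identical_calls_give_zero_difference_unit_p(self):
        ds = _dataset([4.0, 6.0, 5.0], [4.0, 6.0, 5.0])
        cmp = paired_comparison(ds, 5.5)
        assert cmp.difference == 0.0
        assert cmp.mcnemar_p == 1.0
        assert cmp.mcnemar_statistic == 0.0

    def test_hand_computed_table(self):
        """b=30, c=10, n=100: continuity-corrected statistic 9.025."""
        std = [4.0] * 30 + [4.0] * 30 + [7.0] * 10 + [7.0] * 30
        novel = [4.0] * 30 + [7.0] * 30 + [4.0] * 10 + [7.0] * 30
        cmp = paired_comparison(_dataset(std, novel), 5.5)
        assert (cmp.std_only, cmp.novel_only) == (30, 10)
        assert cmp.difference == pytest.approx(-0.20)
        assert cmp.mcnemar_statistic == pytest.approx(9.025)
        assert cmp.mcnemar_p == pytest.approx(0.00266, abs=5e-5)

    def test_difference_equals_sensitivity_difference(self, small_cohort):
        for cutoff in (4.0, 5.0, 5.5, 6.0):
            row = sensitivity_table(small_cohort, cutoffs=(cutoff,)).rows[0]
            assert row.comparison.difference == pytest.approx(
                row.novel.point - row.standard.point, abs=1e-12
            )

    def test_matches_statsmodels_mcnemar(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        rng = np.random.default_rng(0)
        for _ in range(20):
            b, c = rng.integers(0, 40, size=2)
            a = d = 5
            std = [4.0] * a + [4.0] * b + [7.0] * c + [7.0] * d
            novel = [4.0] * a + [7.0] * b + [4.0] * c + [7.0] * d
            if b + c == 0:
                continue
            cmp = paired_comparison(_dataset(std, novel), 5.5)
            ours_cc = cmp.mcnemar_statistic
            ref = sm_mcnemar([[a, b], [c, d]], exact=False, correction=True)
            assert ours_cc == pytest.approx(float(ref.statistic))
            assert cmp.mcnemar_p == pytest.approx(float(ref.pvalue))

    def test_uncorrected_flag(self):
        std = [4.0] * 30 + [7.0] * 10
        novel = [7.0] * 30 + [4.0] * 10
        cmp = paired_comparison(_dataset(std, novel), 5.5, correction=False)
        assert cmp.mcnemar_statistic == pytest.approx((30 - 10) ** 2 / 40)


class TestPairedT:
    def test_zero_variance_is_an_error(self):
        ds = _dataset([5.0, 6.0], [5.0, 6.0])
        with pytest.raises(ValueError, match="zero-variance"):
            paired_t_test(ds)

    def test_symmetric_differences_give_t_zero(self):
        ds = _dataset([5.0, 5.0], [4.5, 5.5])
        res = paired_t_test(ds)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_example(self):
        ds = _dataset([5.0, 6.0, 7.0], [4.0, 5.0, 7.0])
        res = paired_t_test(ds)
        assert res.statistic == pytest.approx(2.0)
        assert res.p_value == pytest.approx(0.1835, abs=1e-3)
        assert res.df == 2


class TestKappa:
    def test_perfect_agreement(self):
        assert cohen_kappa([4.0, 5.0, 6.0], [4.0, 5.0, 6.0]) == 1.0

    def test_independence_gives_zero(self):
        # joint counts exactly proportional to marginal products
        r1 = ["a"] * 4 + ["b"] * 4
        r2 = (["x", "x", "x", "y"]) * 2
        assert cohen_kappa(r1, r2) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_two_categories(self):
        # counts a=45, b=15, c=25, d=15 -> po=0.60, pe=0.54
        r1 = ["+"] * 60 + ["-"] * 40
        r2 = ["+"] * 45 + ["-"] * 15 + ["+"] * 25 + ["-"] * 15
        assert cohen_kappa(r1, r2) == pytest.approx((0.60 - 0.54) / 0.46)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cohen_kappa([1], [1, 2])

    def test_degenerate_identical_constant_vectors(self):
        assert cohen_kappa([5.0] * 10, [5.0] * 10) == 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.sampled_from([3.5, 4.0, 4.5, 5.0, 5.5]), min_size=2, max_size=60),
        st.randoms(use_true_random=False),
    )
    def test_matches_sklearn(self, r1, rnd):
        from sklearn.metrics import cohen_kappa_score

        r2 = [rnd.choice([3.5, 4.0, 4.5, 5.0, 5.5]) for _ in r1]
        # sklearn wants categorical labels, so compare on string ratings
        expected = cohen_kappa_score([str(x) for x in r1], [str(x) for x in r2])
        if math.isnan(expected):  # sklearn's pe=1 convention differs
            return
        assert cohen_kappa(r1, r2) == pytest.approx(expected, abs=1e-12)

    def test_inter_rater_kappa_on_fixture_is_perfect(self, fixture_dataset):
        # fixture sets both readers to the strip value
        assert inter_rater_kappa(fixture_dataset, "standard") == 1.0
        assert inter_rater_kappa(fixture_dataset, "novel") == 1.0

    def test_inter_rater_kappa_above_chance_on_synthetic(self, small_cohort):
        # reader noise (sd 0.25) on a 0.5 grid leaves agreement well above
        # chance but imperfect
        kappa = inter_rater_kappa(small_cohort, "standard")
        assert 0.2 < kappa < 1.0


class TestSampleSize:
    def test_pilot_design_values(self):
        res = sample_size_two_proportions(0.7, 0.9, 0.05, 0.8, 0.0)
        assert res.n_per_group == 62
        res_loss = sample_size_two_proportions(0.7, 0.9, 0.05, 0.8, 0.1)
        assert res_loss.n_per_group_with_loss == 69
        assert res_loss.n_total == 138

    def test_equal_proportions_rejected(self):
        with pytest.raises(ValueError):
            sample_size_two_proportions(0.5, 0.5)

    def test_larger_effect_needs_fewer_patients(self):
        small = sample_size_two_proportions(0.7, 0.75).n_per_group
        large = sample_size_two_proportions(0.7, 0.9).n_per_group
        assert large < small


class TestQCBatchRelease:
    def test_typical_batch_passes(self):
        assert qc_batch_release([4.0, 4.0, 3.5, 4.5, 4.0], [7.0] * 5)

    def test_boundary_five_passes(self):
        assert qc_batch_release([5.0] * 5)

    def test_one_high_reading_fails(self):
        assert not qc_batch_release([4.0, 4.0, 4.0, 4.0, 5.5])

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError):
            qc_batch_release([4.0] * 4)
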