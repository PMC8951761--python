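"""Concordance and reproducibility statistics against published values and oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from xciskew.methylation import Category, Status, XCICall
from xciskew.peak_io import Assay, DegenerateDataError, PairingError
from xciskew.stats import (
    CategoryCounts,
    brown_forsythe,
    chi2_homogeneity,
    concordance_summary,
    kolmogorov_sf,
    ks_two_sample,
    normality_test,
)

TABLE_COUNTS = CategoryCounts(
    labels=("random", "moderate", "high"), counts_a=(36, 6, 6), counts_b=(37, 8, 3)
)


def make_call(sample_id, category, assay=Assay.A, status=Status.OK, borderline=False, skew=None):
    return XCICall(
        sample_id=sample_id,
        assay=assay,
        status=status,
        n_replicates=1,
        repeats=(24, 30) if category is not None else (30,),
        repeat_difference=6 if category is not None else 0,
        bias_ratio=1.0,
        percent_allele1=None,
        percent_allele2=None,
        skew=skew,
        ratio=None,
        category=category,
        borderline=borderline,
    )


class TestChiSquareHomogeneity:
    def test_published_category_counts(self):
        res = chi2_homogeneity(TABLE_COUNTS)
        assert res.partials == pytest.approx((0.013699, 0.285714, 1.0), abs=5e-5)
        assert res.total == pytest.approx(1.2994, abs=5e-4)
        assert res.df == 2
        assert res.p == pytest.approx(0.522, abs=5e-3)

    def test_identical_vectors(self):
        res = chi2_homogeneity(CategoryCounts(("a", "b"), (5, 7), (5, 7)))
        assert res.total == 0.0
        assert res.p == 1.0

    def test_fully_disjoint_hand_case(self):
        res = chi2_homogeneity(CategoryCounts(("a", "b"), (10, 0), (0, 10)))
        assert res.partials == pytest.approx((10.0, 10.0))
        assert res.total == pytest.approx(20.0)

    def test_empty_category_excluded_from_df(self):
        with pytest.warns(UserWarning, match="zero total count"):
            res = chi2_homogeneity(CategoryCounts(("a", "b", "c"), (5, 5, 0), (6, 4, 0)))
        assert res.df == 1
        assert res.partials[2] == 0.0

    @given(
        counts=st.lists(
            st.tuples(st.integers(0, 40), st.integers(0, 40)), min_size=2, max_size=6
        )
    )
    def test_partials_sum_to_total(self, counts):
        a = tuple(c[0] for c in counts)
        b = tuple(c[1] for c in counts)
        populated = sum(x + y > 0 for x, y in counts)
        if sum(a) == 0 or sum(b) == 0 or populated < 2:
            return
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = chi2_homogeneity(CategoryCounts(tuple(map(str, range(len(a)))), a, b))
        assert sum(res.partials) == pytest.approx(res.total, abs=1e-9)
        assert 0.0 <= res.p <= 1.0


class TestKSTwoSample:
    def test_published_category_percentages(self):
        res = ks_two_sample([75, 12.5, 12.5], [77, 16.7, 6.3])
        assert res.D == pytest.approx(1 / 3, abs=5e-4)
        assert 0.975 <= res.p <= 0.977  # published 0.976

    def test_identical_samples(self):
        res = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.D == 0.0
        assert res.p == 1.0

    def test_disjoint_supports(self):
        res = ks_two_sample([1.0, 2.0], [10.0, 11.0, 12.0])
        assert res.D == 1.0

    def test_statistic_matches_scipy(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            x = rng.normal(size=rng.integers(2, 30))
            y = rng.normal(size=rng.integers(2, 30))
            assert ks_two_sample(x, y).D == pytest.approx(
                sps.ks_2samp(x, y).statistic, abs=1e-12
            )

    def test_exact_enumeration_option(self):
        x, y = [1.0, 4.0, 6.0], [2.0, 3.0, 9.0]
        res = ks_two_sample(x, y, method="exact")
        assert res.p == pytest.approx(sps.ks_2samp(x, y, method="exact").pvalue)
        with pytest.raises(ValueError, match="n\\*m"):
            ks_two_sample(list(range(20)), [v + 0.5 for v in range(20)], method="exact")

    @given(
        x=st.lists(st.floats(-50, 50).map(lambda v: round(v, 2)), min_size=1, max_size=12),
        y=st.lists(st.floats(-50, 50).map(lambda v: round(v, 2)), min_size=1, max_size=12),
    )
    def test_symmetry_and_monotone_invariance(self, x, y):
        res = ks_two_sample(x, y)
        assert res.D == pytest.approx(ks_two_sample(y, x).D)
        transform = lambda vals: [math.exp(v / 25.0) for v in vals]
        assert ks_two_sample(transform(x), transform(y)).D == pytest.approx(res.D)
        assert 0.0 <= res.p <= 1.0

    def test_kolmogorov_sf_bounds(self):
        assert kolmogorov_sf(0.0) == 1.0
        assert kolmogorov_sf(10.0) == pytest.approx(0.0, abs=1e-12)


def brute_force_brown_forsythe(groups):
    """Independent oracle: one-way ANOVA on |x - median| from first principles."""
    z = [[abs(v - float(np.median(g))) for v in g] for g in groups]
    all_z = [v for g in z for v in g]
    grand = sum(all_z) / len(all_z)
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in z)
    ss_within = sum((v - sum(g) / len(g)) ** 2 for g in z for v in g)
    df_b = len(z) - 1
    df_w = len(all_z) - len(z)
    F = (ss_between / df_b) / (ss_within / df_w)
    return F, df_b, df_w


class TestBrownForsythe:
    def test_eight_triplicate_groups_df(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(m, 0.5 + m / 10, size=3) for m in range(8)]
        res = brown_forsythe(groups)
        assert res.df_between == 7
        assert res.df_within == 16

    def test_identical_groups_are_homogeneous(self):
        g = [1.0, 2.0, 5.0]
        res = brown_forsythe([g, g, g])
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            groups = [
                rng.normal(rng.uniform(-2, 2), rng.uniform(0.1, 3), size=rng.integers(3, 8))
                for _ in range(rng.integers(2, 6))
            ]
            res = brown_forsythe(groups)
            F, df_b, df_w = brute_force_brown_forsythe(groups)
            assert res.F == pytest.approx(F, abs=1e-9, rel=1e-9)
            assert (res.df_between, res.df_within) == (df_b, df_w)
            assert res.p == pytest.approx(float(sps.f.sf(F, df_b, df_w)), abs=1e-12)

    def test_location_shift_invariance(self):
        groups = [[1.0, 2.0, 4.0], [0.5, 3.0, 3.5], [2.0, 2.5, 6.0]]
        shifted = [groups[0], [v + 100.0 for v in groups[1]], groups[2]]
        assert brown_forsythe(shifted).F == pytest.approx(brown_forsythe(groups).F)

    def test_zero_spread_everywhere_degenerate(self):
        with pytest.raises(DegenerateDataError):
            brown_forsythe([[1.0, 1.0, 1.0], [4.0, 4.0, 4.0]])


class TestNormality:
    def test_constant_sample_rejected(self):
        with pytest.raises(DegenerateDataError):
            normality_test([3.0] * 10)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            normality_test([1.0, 2.0])

    def test_type_i_rate_calibrated(self):
        """Normal data at n=66 rejects near the nominal 5% rate."""
        rng = np.random.default_rng(123)
        rejections = sum(normality_test(rng.normal(size=66))[1] < 0.05 for _ in range(1000))
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_power_against_heavy_tails(self):
        rng = np.random.default_rng(123)
        rejections = sum(
            normality_test(rng.standard_cauchy(size=66))[1] < 0.05 for _ in range(200)
        )
        assert rejections / 200 > 0.5


class TestConcordanceSummary:
    def test_identical_call_sets(self):
        calls = [make_call(f"S{i}", Category.RANDOM) for i in range(10)]
        res = concordance_summary(calls, calls)
        assert res.concordant_fraction == 1.0
        assert res.n_categorized_both == 10

    def test_published_concordant_counts(self):
        """32 random + 3 moderate + 2 high concordant of 48 -> 77%."""
        cats = (
            [Category.RANDOM] * 36 + [Category.MODERATELY_SKEWED] * 6 + [Category.HIGHLY_SKEWED] * 6
        )
        calls_a = [make_call(f"S{i:02d}", c) for i, c in enumerate(cats)]
        flips = (
            list(range(32, 36))  # 4 random -> moderate in B
            + list(range(36 + 3, 36 + 6))  # 3 moderate -> random in B
            + list(range(42 + 2, 48))  # 4 high -> moderate in B
        )
        calls_b = []
        for i, c in enumerate(cats):
            if i in flips:
                c = {
                    Category.RANDOM: Category.MODERATELY_SKEWED,
                    Category.MODERATELY_SKEWED: Category.RANDOM,
                    Category.HIGHLY_SKEWED: Category.MODERATELY_SKEWED,
                }[c]
            calls_b.append(make_call(f"S{i:02d}", c, assay=Assay.B))
        res = concordance_summary(calls_a, calls_b)
        assert res.n_concordant == 32 + 3 + 2
        assert res.concordant_fraction == pytest.approx(37 / 48)
        assert round(100 * res.concordant_fraction) == 77

    def test_uninformative_and_borderline_accounting(self):
        """8 homozygotes + 9 borderline of 74 -> about 23% not defined."""
        calls = []
        for i in range(74):
            if i < 8:
                calls.append(
                    make_call(f"S{i:02d}", None, status=Status.UNINFORMATIVE_HOMOZYGOUS)
                )
            elif i < 17:
                calls.append(
                    make_call(
                        f"S{i:02d}", Category.RANDOM, status=Status.BORDERLINE, borderline=True
                    )
                )
            else:
                calls.append(make_call(f"S{i:02d}", Category.RANDOM))
        res = concordance_summary(calls, calls)
        acct = res.accounting["A"]
        assert acct["uninformative"] == 8
        assert acct["borderline"] == 9
        assert acct["borderline_fraction_informative"] == pytest.approx(9 / 66)
        assert acct["not_defined_fraction"] == pytest.approx(17 / 74)
        assert round(100 * acct["not_defined_fraction"]) == 23

    def test_mismatched_sample_sets_rejected(self):
        a = [make_call("S1", Category.RANDOM)]
        b = [make_call("S2", Category.RANDOM)]
        with pytest.raises(PairingError, match="S1"):
            concordance_summary(a, b)
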