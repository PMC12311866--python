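"""Profile-level inference battery: proportion tests, ANOVAs, strength tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from hlaprofile import (
    Profile,
    ProfileEntry,
    anova_class_gene,
    anova_oneway,
    exact_binomial_two_sided,
    full_report,
    one_sample_proportion_z,
    pairwise_group_means,
    parse_allele,
    sign_counts,
    strength_ttest,
    wald_two_proportion,
)


def _profile_from(names_rprimes, n=10):
    return Profile(
        entries=[
            ProfileEntry(parse_allele(name), n, math.tanh(rp), rp)
            for name, rp in names_rprimes
        ]
    )


class TestSignCounts:
    def test_reference_profile_split(self, reference_profile):
        s = sign_counts(reference_profile)
        assert (s.n_negative, s.n_positive, s.n_zero) == (57, 70, 0)

    def test_class_restricted_splits(self, reference_profile):
        s1 = sign_counts(reference_profile.restrict(hla_class="I"))
        s2 = sign_counts(reference_profile.restrict(hla_class="II"))
        assert (s1.n_negative, s1.n_positive) == (31, 38)
        assert (s2.n_negative, s2.n_positive) == (26, 32)

    def test_zeros_tracked_separately(self):
        p = _profile_from([("A*01:01", 0.0), ("A*02:01", 0.5), ("A*03:01", -0.5)])
        s = sign_counts(p)
        assert (s.n_negative, s.n_positive, s.n_zero) == (1, 1, 1)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            sign_counts(Profile(entries=[]))


class TestProportionZ:
    @pytest.mark.parametrize(
        "k, n, z_expected, p_expected",
        [
            (70, 127, 1.154, 0.249),
            (69, 127, 0.976, 0.329),
            (38, 69, 0.843, 0.399),
            (32, 58, 0.788, 0.431),
        ],
    )
    def test_published_sign_split_statistics(self, k, n, z_expected, p_expected):
        z, p = one_sample_proportion_z(k, n, 0.5)
        assert z == pytest.approx(z_expected, abs=1e-3)
        assert p == pytest.approx(p_expected, abs=1e-3)

    def test_null_center(self):
        z, p = one_sample_proportion_z(50, 100, 0.5)
        assert (z, p) == (0.0, 1.0)

    @settings(derandomize=True, max_examples=50)
    @given(n=st.integers(1, 300), k=st.integers(0, 300))
    def test_symmetry_in_magnitude(self, n, k):
        k = min(k, n)
        z1, p1 = one_sample_proportion_z(k, n, 0.5)
        z2, p2 = one_sample_proportion_z(n - k, n, 0.5)
        assert z1 == pytest.approx(z2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            one_sample_proportion_z(1, 0)
        with pytest.raises(ValueError):
            one_sample_proportion_z(5, 4)
        with pytest.raises(ValueError):
            one_sample_proportion_z(1, 4, 1.0)


class TestExactBinomial:
    def test_tail_enumeration(self):
        assert exact_binomial_two_sided(0, 5, 0.5) == pytest.approx(0.0625, abs=1e-12)

    def test_mode_gives_one(self):
        assert exact_binomial_two_sided(5, 10, 0.5) == pytest.approx(1.0)

    @pytest.mark.parametrize("k, n, p0", [(70, 127, 0.5), (3, 20, 0.3), (17, 19, 0.6)])
    def test_matches_full_enumeration_oracle(self, k, n, p0):
        # oracle: sum the probability of every outcome at most as likely as k
        pk = sps.binom.pmf(k, n, p0)
        total = sum(
            sps.binom.pmf(j, n, p0)
            for j in range(n + 1)
            if sps.binom.pmf(j, n, p0) <= pk * (1 + 1e-10)
        )
        assert exact_binomial_two_sided(k, n, p0) == pytest.approx(total, abs=1e-12)

    def test_converges_to_normal_approximation(self):
        # same standardized deviation (z ~ 2.2) at n = 100 and n = 1000:
        # the gap to the normal approximation shrinks below 0.005
        def gap(k, n):
            exact = exact_binomial_two_sided(k, n, 0.5)
            _, approx = one_sample_proportion_z(k, n, 0.5)
            return abs(exact - approx)

        assert gap(535, 1000) < 0.005
        assert gap(535, 1000) < gap(61, 100)


class TestWald:
    def test_equal_proportions(self):
        z, p = wald_two_proportion(5, 10, 5, 10)
        assert (z, p) == (0.0, 1.0)

    def test_matches_hand_formula(self):
        k1, n1, k2, n2 = 31, 69, 26, 58
        p1, p2 = k1 / n1, k2 / n2
        se = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
        z, p = wald_two_proportion(k1, n1, k2, n2)
        assert z == pytest.approx((p1 - p2) / se, abs=1e-12)
        assert p == pytest.approx(2 * sps.norm.sf(abs(z)), abs=1e-12)

    def test_strong_imbalance_is_significant(self):
        z, p = wald_two_proportion(9, 10, 1, 10)
        assert z > 0 and p < 0.05

    def test_doubly_degenerate_rejected(self):
        with pytest.raises(ValueError):
            wald_two_proportion(10, 10, 0, 5)


class TestOneWayAnova:
    def test_reference_profile_by_sample_size(self, reference_profile):
        F, dfb, dfw, p = anova_oneway(
            reference_profile.r_prime, reference_profile.n_countries
        )
        assert (dfb, dfw) == (5, 121)
        assert F == pytest.approx(1.185, abs=0.01)
        assert p == pytest.approx(0.32, abs=0.01)

    def test_f_equals_t_squared_for_two_groups(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(0, 1, 12), rng.normal(0.4, 1, 9)
        F, dfb, dfw, _ = anova_oneway(
            np.concatenate([a, b]), ["a"] * 12 + ["b"] * 9
        )
        t, _ = sps.ttest_ind(a, b, equal_var=True)
        assert F == pytest.approx(t**2, abs=1e-10)

    def test_sum_of_squares_partition(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=30)
        groups = np.repeat(["a", "b", "c"], 10)
        grand = values.mean()
        ss_total = ((values - grand) ** 2).sum()
        ss_between = sum(
            10 * (values[groups == g].mean() - grand) ** 2 for g in "abc"
        )
        ss_within = sum(
            ((values[groups == g] - values[groups == g].mean()) ** 2).sum()
            for g in "abc"
        )
        assert ss_total == pytest.approx(ss_between + ss_within, abs=1e-10)
        F, dfb, dfw, _ = anova_oneway(values, groups)
        assert F == pytest.approx((ss_between / dfb) / (ss_within / dfw), abs=1e-10)

    def test_identical_group_means_give_zero_f(self):
        values = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        F, *_ = anova_oneway(values, ["a"] * 3 + ["b"] * 3)
        assert F == pytest.approx(0.0, abs=1e-12)

    def test_all_identical_values_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([1.0] * 6, ["a"] * 3 + ["b"] * 3)


class TestPairwiseMeans:
    def test_reference_profile_no_pair_differs(self, reference_profile):
        rows = pairwise_group_means(
            reference_profile.r_prime, reference_profile.n_countries
        )
        assert len(rows) == 15  # C(6, 2) sample-size groups
        assert all(r["p_adjusted"] > 0.05 for r in rows)

    def test_identical_groups(self):
        rows = pairwise_group_means([1.0, 2.0, 1.0, 2.0], ["a", "a", "b", "b"])
        assert rows[0]["mean_difference"] == 0.0
        assert rows[0]["p_value"] == pytest.approx(1.0)

    def test_single_shifted_group_detected(self):
        rng = np.random.default_rng(4)
        values = np.concatenate(
            [rng.normal(0, 0.2, 15), rng.normal(0, 0.2, 15), rng.normal(3, 0.2, 15)]
        )
        groups = np.repeat(["a", "b", "c"], 15)
        rows = pairwise_group_means(values, groups)
        sig = {tuple(r["groups"]) for r in rows if r["p_adjusted"] < 0.05}
        assert sig == {("a", "c"), ("b", "c")}


class TestNestedAnova:
    def test_reference_profile_df_bookkeeping(self, reference_profile):
        rows = anova_class_gene(reference_profile)
        by_name = {r["test"]: r for r in rows}
        assert by_name["anova_class"]["df"] == [1, 121]
        assert by_name["anova_gene_within_class"]["df"] == [4, 121]

    def test_gene_error_term_option(self, reference_profile):
        rows = anova_class_gene(reference_profile, class_error_term="gene")
        cls = [r for r in rows if r["test"] == "anova_class"][0]
        assert cls["df"] == [1, 4]

    def test_pure_class_effect(self):
        # class II entries shifted by +2: class F large, gene(class) F modest
        rng = np.random.default_rng(9)
        entries = []
        for locus, count in [("A", 8), ("B", 8), ("C", 8)]:
            for i in range(count):
                entries.append((f"{locus}*{i + 1:02d}:01", rng.normal(0.0, 0.1)))
        for locus, count in [("DPB1", 8), ("DQB1", 8), ("DRB1", 8)]:
            for i in range(count):
                entries.append((f"{locus}*{i + 1:02d}:01", rng.normal(2.0, 0.1)))
        rows = anova_class_gene(_profile_from(entries))
        by_name = {r["test"]: r for r in rows}
        assert by_name["anova_class"]["p_value"] < 1e-6
        assert by_name["anova_gene_within_class"]["statistic"] < 5.0

    def test_all_equal_values_flagged(self):
        p = _profile_from(
            [("A*01:01", 0.3), ("A*02:01", 0.3), ("DQB1*03:01", 0.3), ("DQB1*03:02", 0.3)]
        )
        with pytest.raises(ValueError):
            anova_class_gene(p)


class TestStrengthTTests:
    def test_reference_profile_all_nonsignificant(self, reference_profile):
        for split in ("class", "gene"):
            rows = strength_ttest(reference_profile, split_by=split)
            assert rows, split
            assert all(r["p_value"] > 0.05 for r in rows)

    def test_group_against_itself(self):
        vals = [0.5, 0.7, 0.9, -0.5, -0.7, -0.9]
        p = _profile_from(
            [(f"A*{i + 1:02d}:01", v) for i, v in enumerate(vals)]
        )
        rows = strength_ttest(p, split_by="class")
        assert rows[0]["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert rows[0]["p_value"] == pytest.approx(1.0)

    def test_shifted_negative_group_detected(self):
        rng = np.random.default_rng(8)
        entries = []
        for i in range(12):
            entries.append((f"A*{i + 1:02d}:01", -(1.5 + rng.normal(0, 0.1))))
        for i in range(12):
            entries.append((f"B*{i + 1:02d}:01", 0.3 + rng.normal(0, 0.1)))
        rows = strength_ttest(_profile_from(entries), split_by="class")
        # class I mixes strongly negative and weakly positive entries
        assert rows[0]["p_value"] < 0.01

    def test_small_cells_skipped_with_warning(self):
        p = _profile_from([("A*01:01", -0.5), ("A*02:01", 0.5), ("A*03:01", 0.6)])
        with pytest.warns(UserWarning, match="skipped"):
            rows = strength_ttest(p, split_by="gene")
        assert rows == []


class TestFullReport:
    def test_reference_profile_battery(self, reference_profile):
        report = full_report(reference_profile)
        assert report.warnings == []
        by_name = {t["test"]: t for t in report.tests}
        overall = by_name["sign_split_overall"]
        assert overall["group_sizes"][:2] == [57, 70]
        assert overall["statistic"] == pytest.approx(1.154, abs=1e-3)
        assert by_name["class_membership_split"]["statistic"] == pytest.approx(
            0.976, abs=1e-3
        )
        assert by_name["anova_by_sample_size"]["statistic"] == pytest.approx(
            1.185, abs=0.01
        )
        strength = [t for t in report.tests if t["test"].startswith("strength")]
        assert len(strength) == 2 + 6  # per class and per gene
        assert all(t["p_value"] > 0.05 for t in strength)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            full_report(Profile(entries=[]))

    def test_failing_component_is_isolated(self):
        # two alleles per class, all r' equal: sign tests fine, ANOVA undefined
        p = _profile_from(
            [
                ("A*01:01", 0.3),
                ("B*01:01", 0.3),
                ("DQB1*03:01", 0.3),
                ("DRB1*01:01", 0.3),
            ]
        )
        report = full_report(p)
        assert any("anova" in w for w in report.warnings)
        assert report.find("sign_split_overall")
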