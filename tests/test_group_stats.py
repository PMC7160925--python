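"""Summary-statistic tests, compact letter displays, diagnostics and repeatability.

The central property: tests computed from (n, mean, sd) summaries are
exactly equal to their raw-data counterparts when the summaries come,
unrounded, from the raw data.
"""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from csia_trophic import (
    GroupSummary,
    anova_from_summaries,
    levene_test,
    paired_t,
    repeatability,
    shapiro_wilk,
    tukey_cld,
    welch_t_from_summaries,
)
from csia_trophic.errors import (
    DegenerateVarianceError,
    InsufficientDataError,
)
from csia_trophic.stats import cld_from_significance, tukey_pairwise_p


def summaries_of(groups):
    return [GroupSummary.from_values(str(i), g) for i, g in enumerate(groups)]


class TestWelch:
    def test_identical_summaries_give_t_zero_p_one(self):
        g = GroupSummary("a", 5, 3.5, 0.2)
        rep = welch_t_from_summaries(g, GroupSummary("b", 5, 3.5, 0.2))
        assert rep.statistic == 0.0
        assert rep.p_value == pytest.approx(1.0)

    def test_hand_evaluated_statistic_and_df(self):
        # equal SDs and ns: t = 0.8/sqrt(2*0.04/5) = 6.3246, df = 8 exactly
        rep = welch_t_from_summaries(
            GroupSummary("breeding", 5, 3.7, 0.2), GroupSummary("moult", 5, 2.9, 0.2)
        )
        assert rep.statistic == pytest.approx(6.32455532, abs=1e-6)
        assert rep.df == pytest.approx(8.0)

    def test_welch_satterthwaite_df_unequal_variances(self):
        rep = welch_t_from_summaries(
            GroupSummary("a", 5, 3.9, 0.1), GroupSummary("b", 5, 3.3, 0.3)
        )
        assert rep.df == pytest.approx(4.878, abs=1e-3)
        assert round(rep.df, 1) == 4.9

    def test_matches_scipy_from_stats_and_raw_data(self, rng):
        for _ in range(25):
            a = rng.normal(0, 1, size=int(rng.integers(3, 12)))
            b = rng.normal(0.5, 2, size=int(rng.integers(3, 12)))
            sa, sb = summaries_of([a, b])
            rep = welch_t_from_summaries(sa, sb)
            t_ref, p_ref = sps.ttest_ind(a, b, equal_var=False)
            assert rep.statistic == pytest.approx(t_ref, rel=1e-12)
            assert rep.p_value == pytest.approx(p_ref, rel=1e-9)

    def test_one_sided_p_halves_two_sided(self):
        a, b = GroupSummary("a", 5, 3.9, 0.2), GroupSummary("b", 5, 3.3, 0.2)
        two = welch_t_from_summaries(a, b, "two_sided").p_value
        greater = welch_t_from_summaries(a, b, "greater").p_value
        less = welch_t_from_summaries(a, b, "less").p_value
        assert two == pytest.approx(2 * min(greater, less))

    def test_insufficient_data_rejected(self):
        with pytest.raises(InsufficientDataError):
            welch_t_from_summaries(GroupSummary("a", 1, 0.0), GroupSummary("b", 5, 0.0, 1.0))


class TestPairedT:
    def test_zero_variance_differences_are_degenerate(self):
        with pytest.raises(DegenerateVarianceError):
            paired_t([1.0, 1.0, 1.0, 1.0])

    def test_antisymmetry(self):
        d = [0.4, -0.1, 0.3, 0.6, 0.2]
        pos = paired_t(d)
        neg = paired_t([-x for x in d])
        assert neg.statistic == pytest.approx(-pos.statistic)
        assert neg.p_value == pytest.approx(pos.p_value)

    def test_df_is_n_minus_one_and_matches_raw_oracle(self):
        """Eight breeding-vs-moult pairs: df = 7 always; p identical to the
        one-sample t oracle, and the α=0.05 rejection rate over 500 seeds
        matches it exactly."""
        rejections_ours = rejections_oracle = 0
        for seed in range(500):
            rng = np.random.default_rng(seed)
            d = rng.normal(0.3, 0.3, size=8)
            rep = paired_t(d)
            assert rep.df == 7.0
            t_ref, p_ref = sps.ttest_1samp(d, 0.0)
            assert rep.statistic == pytest.approx(t_ref, rel=1e-12)
            assert rep.p_value == pytest.approx(p_ref, rel=1e-9)
            rejections_ours += rep.p_value < 0.05
            rejections_oracle += p_ref < 0.05
        assert rejections_ours == rejections_oracle
        # theoretical power at delta=0.3, sd=0.3, n=8 is ~0.66; loose sanity band
        assert 0.5 < rejections_ours / 500 < 0.8


class TestAnova:
    def test_equal_means_give_f_zero(self):
        groups = [GroupSummary(l, 5, 2.0, s) for l, s in zip("abc", (0.1, 0.2, 0.3))]
        rep = anova_from_summaries(groups)
        assert rep.statistic == 0.0
        assert rep.p_value == pytest.approx(1.0)

    def test_df_structure_four_groups_of_five(self):
        groups = [GroupSummary(l, 5, m, 0.5) for l, m in zip("abcd", (1, 2, 3, 4))]
        rep = anova_from_summaries(groups)
        assert rep.df == (3.0, 16.0)

    def test_equals_raw_data_anova_on_generated_datasets(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 6))
            data = [
                rng.normal(rng.normal(0, 1), rng.uniform(0.5, 2), size=int(rng.integers(2, 10)))
                for _ in range(k)
            ]
            rep = anova_from_summaries(summaries_of(data))
            f_ref, p_ref = sps.f_oneway(*data)
            assert rep.statistic == pytest.approx(f_ref, rel=1e-10)
            assert rep.p_value == pytest.approx(p_ref, rel=1e-8)
            assert rep.df == (k - 1, sum(len(d) for d in data) - k)

    def test_group_of_one_rejected(self):
        with pytest.raises(InsufficientDataError):
            anova_from_summaries([GroupSummary("a", 1, 0.0), GroupSummary("b", 5, 1.0, 1.0)])


def exact_summary_data(rng, mean, sd, n):
    """Raw values whose sample mean and SD are exactly the requested ones."""
    z = rng.normal(size=n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z


class TestTukeyCLD:
    def test_overwhelming_separation_gets_distinct_letters(self):
        groups = [GroupSummary("lo", 5, 0.0, 1.0), GroupSummary("hi", 5, 100.0, 1.0)]
        res = tukey_cld(groups)
        assert res.letters["lo"] == "a"
        assert res.letters["hi"] == "b"

    def test_identical_groups_share_a_letter(self):
        groups = [GroupSummary(l, 5, 1.0, 0.5) for l in "abcd"]
        res = tukey_cld(groups)
        assert all(v == "a" for v in res.letters.values())

    def test_pairwise_p_matches_raw_data_tukeyhsd(self, rng):
        """Tukey–Kramer from summaries equals statsmodels on raw data whose
        summaries are exact (unequal n included)."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        means, sds, ns = (0.0, 0.5, 1.5, 3.0), (0.8, 1.0, 1.2, 0.9), (5, 7, 4, 6)
        data, labels = [], []
        for i, (m, s, n) in enumerate(zip(means, sds, ns)):
            data.append(exact_summary_data(rng, m, s, n))
            labels += [str(i)] * n
        res = pairwise_tukeyhsd(np.concatenate(data), labels)
        ours = tukey_pairwise_p(summaries_of(data))
        pairs = list(itertools.combinations(res.groupsunique, 2))
        assert len(pairs) == len(res.pvalues)
        for (g1, g2), p_ref in zip(pairs, res.pvalues):
            assert ours[(str(g1), str(g2))] == pytest.approx(p_ref, abs=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_letter_partition_matches_bruteforce_significance(self, seed):
        """On 4-group cases patterned on the breeding-season δ13C structure
        (three overlapping + one distant), groups share a letter iff their
        pairwise comparison is non-significant."""
        rng = np.random.default_rng(seed)
        means = [-17.1, -17.5, -18.1, -19.8] + rng.normal(0, 0.3, size=4)
        groups = [
            GroupSummary(f"g{i}", 5, float(m), float(rng.uniform(0.2, 0.8)))
            for i, m in enumerate(means)
        ]
        res = tukey_cld(groups, alpha=0.05)
        for a, b in itertools.combinations([g.label for g in groups], 2):
            p = res.pairwise_p[(a, b)]
            assert res.share_letter(a, b) == (p >= 0.05)

    def test_permuting_groups_permutes_labels_not_partition(self):
        groups = [
            GroupSummary("w", 5, 0.0, 0.5),
            GroupSummary("x", 5, 0.4, 0.5),
            GroupSummary("y", 5, 3.0, 0.5),
            GroupSummary("z", 5, 3.3, 0.5),
        ]
        res_fwd = tukey_cld(groups)
        res_rev = tukey_cld(groups[::-1])
        for a, b in itertools.combinations("wxyz", 2):
            assert res_fwd.share_letter(a, b) == res_rev.share_letter(a, b)

    def test_cld_insert_absorb_on_explicit_matrix(self):
        # chain a-b n.s., b-c n.s., a-c significant -> letters overlap pairwise
        sig = {("a", "b"): False, ("b", "c"): False, ("a", "c"): True}
        letters = cld_from_significance(["a", "b", "c"], sig)
        assert set(letters["a"]) & set(letters["b"])
        assert set(letters["b"]) & set(letters["c"])
        assert not set(letters["a"]) & set(letters["c"])


class TestDiagnostics:
    def test_levene_type_one_error_near_alpha(self):
        rejections = 0
        n_rep = 1000
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            groups = {l: rng.normal(0, 1, size=20) for l in "ab"}
            rejections += levene_test(groups).p_value < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_levene_detects_tenfold_scale_difference(self, rng):
        groups = {"a": rng.normal(0, 1, size=50), "b": rng.normal(0, 10, size=50)}
        assert levene_test(groups).p_value < 0.001

    def test_levene_df_structure(self, rng):
        groups = {l: rng.normal(0, 1, size=10) for l in "abc"}
        assert levene_test(groups).df == (2.0, 27.0)

    def test_shapiro_rejects_uniform_data(self):
        rejections = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            rejections += shapiro_wilk(rng.uniform(size=100)).p_value < 0.01
        assert rejections / n_rep >= 0.95

    def test_shapiro_size_limits(self):
        with pytest.raises(InsufficientDataError):
            shapiro_wilk([1.0, 2.0])


class TestRepeatability:
    def test_exact_duplicates_are_fully_repeatable(self):
        assert repeatability([(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)]) == pytest.approx(100.0)

    def test_equal_between_and_within_variance_gives_fifty_percent(self):
        estimates = []
        for seed in range(500):
            rng = np.random.default_rng(seed)
            true = rng.normal(0, 0.3, size=30)
            pairs = true[:, None] + rng.normal(0, 0.3, size=(30, 2))
            estimates.append(repeatability(pairs))
        assert np.mean(estimates) == pytest.approx(50.0, abs=5.0)

    def test_recovers_constructed_icc_of_ninety_percent(self):
        sigma_b = 0.3
        sigma_e = sigma_b * np.sqrt(1 / 0.9 - 1)
        estimates = []
        for seed in range(500):
            rng = np.random.default_rng(seed)
            true = rng.normal(0, sigma_b, size=30)
            pairs = true[:, None] + rng.normal(0, sigma_e, size=(30, 2))
            estimates.append(repeatability(pairs))
        assert np.mean(estimates) == pytest.approx(90.0, abs=2.0)

    def test_needs_three_pairs(self):
        with pytest.raises(InsufficientDataError):
            repeatability([(1.0, 1.1), (2.0, 2.1)])
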