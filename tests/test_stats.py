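import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thyquant.stats import (
    ManualScorePair,
    diagnostic_metrics,
    emulate_manual_score,
    final_manual_score,
    lin_ccc,
    oneway_anova_pairwise,
    pearson_r,
    percent_to_pscore,
    shapiro_wilk,
)


class TestManualScoring:
    @pytest.mark.parametrize(
        "percent,expected",
        [(5, 0), (10, 0), (11, 1), (30, 1), (45, 2), (50, 2), (51, 3), (70, 3), (71, 4), (85, 4), (100, 4)],
    )
    def test_percentage_bins_with_lower_boundary_convention(self, percent, expected):
        assert percent_to_pscore(percent) == expected

    def test_out_of_range_percent_rejected(self):
        with pytest.raises(ValueError):
            percent_to_pscore(101)
        with pytest.raises(ValueError):
            percent_to_pscore(-1)

    def test_maximal_scores_reach_seven(self):
        assert final_manual_score(ManualScorePair(4, 3, 4, 3)) == 7.0

    def test_zero_case(self):
        assert final_manual_score(ManualScorePair(0, 0, 0, 0)) == 0.0

    def test_printed_formula_arithmetic(self):
        assert final_manual_score(ManualScorePair(2, 1, 3, 2)) == 4.0

    def test_full_enumeration_bounded_and_symmetric(self):
        """All 400 evaluator combinations stay in [0, 7] and swap-invariant."""
        seen = set()
        for p1, i1, p2, i2 in itertools.product(range(5), range(4), range(5), range(4)):
            s = final_manual_score(ManualScorePair(p1, i1, p2, i2))
            swapped = final_manual_score(ManualScorePair(p2, i2, p1, i1))
            assert s == swapped
            assert 0.0 <= s <= 7.0
            assert s * 2 == int(s * 2)  # half-integer grid
            seen.add(s)
        assert max(seen) == 7.0 and min(seen) == 0.0

    def test_invalid_subscores_rejected(self):
        with pytest.raises(ValueError):
            ManualScorePair(5, 0, 0, 0)
        with pytest.raises(ValueError):
            ManualScorePair(0, 4, 0, 0)

    def test_emulated_score_tracks_staining_strength(self):
        weak = emulate_manual_score(5.0, 240.0)
        strong = emulate_manual_score(90.0, 90.0)
        assert weak < strong <= 7.0


def _ccc_brute(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    mx, my = x.mean(), y.mean()
    sx2 = ((x - mx) ** 2).sum() / n
    sy2 = ((y - my) ** 2).sum() / n
    sxy = ((x - mx) * (y - my)).sum() / n
    return 2 * sxy / (sx2 + sy2 + (mx - my) ** 2)


class TestConcordance:
    def test_identity_is_perfectly_concordant(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        rc, (lo, hi) = lin_ccc(x, x)
        assert rc == 1.0 and lo == 1.0 and hi == 1.0

    def test_constant_second_vector_gives_zero(self):
        rc, _ = lin_ccc([1.0, 2.0, 3.0, 4.0], [2.0, 2.0, 2.0, 2.0])
        assert rc == 0.0

    def test_matches_direct_formula(self):
        x = (1.0, 2.0, 3.0, 4.0)
        y = (1.5, 2.5, 3.5, 4.5)
        rc, _ = lin_ccc(x, y)
        assert rc == pytest.approx(_ccc_brute(x, y), abs=1e-12)

    def test_location_shift_penalised_but_pearson_unmoved(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(0, 0.1, size=30)
        rc0, _ = lin_ccc(x, y)
        rc1, _ = lin_ccc(x, y + 1.5)
        assert rc1 < rc0
        assert pearson_r(x, y + 1.5) == pytest.approx(pearson_r(x, y))

    def test_concordance_never_exceeds_correlation(self, rng):
        for _ in range(20):
            x = rng.normal(size=12)
            y = rng.normal(size=12) + 0.5 * x
            rc, _ = lin_ccc(x, y)
            assert abs(rc) <= abs(pearson_r(x, y)) + 1e-12

    def test_doubly_constant_input_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            lin_ccc([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])

    def test_ci_brackets_estimate(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(0, 0.5, size=40)
        rc, (lo, hi) = lin_ccc(x, y)
        assert lo <= rc <= hi


class TestPearson:
    def test_proportional_vectors(self):
        assert pearson_r([1, 2, 3, 4], [2, 4, 6, 8]) == pytest.approx(1.0)
        assert pearson_r([1, 2, 3, 4], [-1, -2, -3, -4]) == pytest.approx(-1.0)

    def test_matches_direct_formula(self, rng):
        x = rng.normal(size=9)
        y = rng.normal(size=9)
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert pearson_r(x, y) == pytest.approx(num / den, abs=1e-12)


def _anova_f_brute(groups):
    all_v = np.concatenate(groups)
    grand = all_v.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    dfb, dfw = len(groups) - 1, len(all_v) - len(groups)
    return (ssb / dfb) / (ssw / dfw)


def _table(**groups):
    rows = [
        {"group": g, "value": v} for g, vals in groups.items() for v in vals
    ]
    return pd.DataFrame(rows)


class TestAnova:
    def test_identical_groups_show_null_contrast(self):
        t = _table(a=[1.0, 2.0, 3.0, 4.0], b=[1.0, 2.0, 3.0, 4.0])
        rep = oneway_anova_pairwise(t, "value", "a")
        row = rep.pairwise.iloc[0]
        assert row.mean_difference == 0.0
        assert row.p_adj > 0.99
        assert row.ci_low <= 0.0 <= row.ci_high

    def test_f_statistic_matches_sum_of_squares(self):
        g = ([1.0, 2.0, 2.5], [3.0, 3.5, 4.0], [6.0, 7.0, 8.0])
        t = _table(a=g[0], b=g[1], c=g[2])
        rep = oneway_anova_pairwise(t, "value", "a")
        assert rep.f_statistic == pytest.approx(_anova_f_brute(g), abs=1e-10)

    def test_overall_p_invariant_to_relabeling(self, rng):
        vals = {k: rng.normal(i, 1, 8).tolist() for i, k in enumerate("abc")}
        p1 = oneway_anova_pairwise(_table(**vals), "value", "a").p_value
        relabeled = {"c": vals["a"], "a": vals["b"], "b": vals["c"]}
        p2 = oneway_anova_pairwise(_table(**relabeled), "value", "a").p_value
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_tukey_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        t = _table(
            a=rng.normal(0, 1, 10).tolist(),
            b=rng.normal(1, 1, 12).tolist(),
            c=rng.normal(2, 1, 9).tolist(),
        )
        rep = oneway_anova_pairwise(t, "value", "a", adjustment="tukey")
        sm = pairwise_tukeyhsd(t["value"], t["group"])
        pairs = list(itertools.combinations(sm.groupsunique, 2))
        for _, row in rep.pairwise.iterrows():
            i = pairs.index(("a", row.group_j))
            # statsmodels reports group2 - group1; ours is reference - other
            assert row.mean_difference == pytest.approx(-sm.meandiffs[i], abs=1e-9)
            assert row.p_adj == pytest.approx(sm.pvalues[i], abs=1e-6)

    def test_undersized_group_named(self):
        t = _table(a=[1.0, 2.0], b=[3.0])
        with pytest.raises(ValueError, match="'b'"):
            oneway_anova_pairwise(t, "value", "a")

    def test_pairwise_ci_contains_mean_difference(self, rng):
        t = _table(a=rng.normal(0, 1, 15).tolist(), b=rng.normal(2, 1, 15).tolist())
        for adj in ("tukey", "bonferroni", "lsd"):
            rep = oneway_anova_pairwise(t, "value", "a", adjustment=adj)
            row = rep.pairwise.iloc[0]
            assert row.ci_low <= row.mean_difference <= row.ci_high


class TestShapiroWilk:
    def test_tiny_or_constant_samples_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(ValueError):
            shapiro_wilk([2.0] * 10)

    def test_skewed_samples_rejected_with_high_power(self):
        rejections = 0
        for seed in range(50):
            v = np.random.default_rng(seed).exponential(size=100)
            _, p = shapiro_wilk(v)
            rejections += p < 0.05
        assert rejections >= 48  # >= 95% power against exponential data

    def test_normal_samples_usually_pass(self):
        rejections = 0
        for seed in range(50):
            v = np.random.default_rng(seed).normal(size=100)
            _, p = shapiro_wilk(v)
            rejections += p < 0.05
        assert rejections <= 7


def _auc_brute(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestDiagnosticMetrics:
    def test_perfect_separation(self):
        rep = diagnostic_metrics([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert rep.auc == 1.0
        assert rep.proportion_misclassified == 0.0
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_auc_matches_pair_counting_with_ties(self):
        scores = [1.0, 2.0, 2.0, 3.0, 3.0, 5.0]
        labels = [0, 0, 1, 0, 1, 1]
        rep = diagnostic_metrics(scores, labels)
        assert rep.auc == pytest.approx(_auc_brute(scores, labels), abs=1e-12)

    def test_permuted_labels_give_chance_auc(self):
        rng = np.random.default_rng(77)
        scores = rng.normal(size=2000)
        labels = rng.permutation([0] * 1000 + [1] * 1000)
        rep = diagnostic_metrics(scores, labels)
        assert rep.auc == pytest.approx(0.5, abs=0.03)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            diagnostic_metrics([1.0, 2.0], [1, 1])

    def test_confusion_matrix_consistency(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 50), rng.normal(1, 1, 50)])
        labels = np.array([0] * 50 + [1] * 50)
        rep = diagnostic_metrics(scores, labels)
        # misclassification decomposes into the two error rates
        expected = 0.5 * (1 - rep.sensitivity) + 0.5 * (1 - rep.specificity)
        assert rep.proportion_misclassified == pytest.approx(expected, abs=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    p1=st.integers(0, 4), i1=st.integers(0, 3),
    p2=st.integers(0, 4), i2=st.integers(0, 3),
)
def test_manual_score_equals_average_of_evaluator_totals(p1, i1, p2, i2):
    s = final_manual_score(ManualScorePair(p1, i1, p2, i2))
    assert s == ((p1 + i1) + (p2 + i2)) / 2
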