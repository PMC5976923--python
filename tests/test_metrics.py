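"""Confusion metrics, ROC/AUC rank identity, group assignment, ANOVA and
the published-cohort worked examples."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from erpspeller import metrics as mx
from erpspeller.decoder import TrialDecision


def _decision(selected, target):
    return TrialDecision(0, (0.5,) * 6, (False,) * 6, selected, "no_target",
                         target, False)


class TestConfusion:
    def test_from_labels_counts(self):
        c = mx.ConfusionCounts.from_labels([1, 1, 0, 0, 1], [1, 0, 0, 1, 1])
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 1, 1, 1)
        assert c.total == 5

    def test_sensitivity_precision_arithmetic(self):
        c = mx.ConfusionCounts(tp=3, fp=0, tn=0, fn=1)
        assert mx.sensitivity(c) == 0.75
        c = mx.ConfusionCounts(tp=0, fp=5, tn=0, fn=0)
        assert mx.precision(c) == 0.0

    def test_zero_denominators_are_missing(self):
        assert math.isnan(mx.sensitivity(mx.ConfusionCounts(0, 3, 4, 0)))
        assert math.isnan(mx.precision(mx.ConfusionCounts(0, 0, 4, 2)))

    def test_random_counts_match_formulas(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            tp, fp, tn, fn = rng.integers(1, 50, size=4)
            c = mx.ConfusionCounts(int(tp), int(fp), int(tn), int(fn))
            assert mx.sensitivity(c) == tp / (fn + tp)
            assert mx.precision(c) == tp / (tp + fp)
            assert mx.eq_correct_rate(c) == (tp + tn) / (tp + tn + fp + fn)

    def test_eq_correct_rate_example(self):
        assert mx.eq_correct_rate(mx.ConfusionCounts(3, 1, 5, 1)) == 0.8
        assert mx.eq_correct_rate(mx.ConfusionCounts(3, 0, 5, 0)) == 1.0


class TestF1:
    @pytest.mark.parametrize("sens,prec,expected", [
        (0.647, 0.131, 0.218),   # published worked examples
        (0.846, 0.344, 0.489),
    ])
    def test_published_rows(self, sens, prec, expected):
        assert mx.round3(mx.f1_measure(sens, prec)) == expected

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(min_value=1e-3, max_value=1.0))
    def test_harmonic_mean_of_equals(self, x):
        assert mx.f1_measure(x, x) == pytest.approx(x, rel=1e-12)

    def test_zero_sum_missing(self):
        assert math.isnan(mx.f1_measure(0.0, 0.0))


class TestTrialAccuracy:
    def test_eleven_of_twelve(self):
        decs = [_decision(0, 0)] * 11 + [_decision(1, 0)]
        assert mx.round3(mx.trial_accuracy(decs)) == 0.917

    def test_all_correct(self):
        assert mx.trial_accuracy([_decision(2, 2)] * 12) == 1.0

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(1)
        decs = [_decision(int(rng.integers(6)), int(rng.integers(6)))
                for _ in range(3000)]
        assert mx.trial_accuracy(decs) == pytest.approx(1 / 6, abs=0.03)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mx.trial_accuracy([])


class TestRocAuc:
    def test_perfect_separation(self):
        assert mx.roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores(self):
        assert mx.roc_auc([0.5] * 10, [1, 0] * 5) == 0.5

    def test_pairwise_oracle_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            scores = np.round(rng.random(20), 2)  # provoke ties
            truth = rng.random(20) < 0.4
            if truth.all() or not truth.any():
                continue
            pos, neg = scores[truth], scores[~truth]
            wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
            oracle = wins / (len(pos) * len(neg))
            assert abs(mx.roc_auc(scores, truth) - oracle) <= 1e-12

    def test_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(4)
        scores = rng.random(50)
        truth = rng.random(50) < 0.5
        assert mx.roc_auc(scores, truth) == pytest.approx(
            roc_auc_score(truth, scores), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        scores = rng.random(30)
        truth = rng.random(30) < 0.5
        assert mx.roc_auc(np.exp(5 * scores), truth) == pytest.approx(
            mx.roc_auc(scores, truth), abs=1e-12)

    def test_single_class_missing(self):
        assert math.isnan(mx.roc_auc([0.1, 0.9], [1, 1]))


class TestGroupAssignment:
    @pytest.mark.parametrize("rate,group", [(0.6, "H"), (0.4, "L"), (0.5, "L")])
    def test_threshold(self, rate, group):
        assert mx.assign_group(rate) == group

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mx.assign_group(1.2)


class TestAnova:
    def test_identical_groups_f_zero(self):
        assert mx.anova_oneway([1.0, 1.0, 1.0], [1.0, 1.0]) == (0.0, 1.0)

    def test_hand_computed_example(self):
        f, p = mx.anova_oneway([1, 2, 3], [4, 5, 6])
        assert f == pytest.approx(13.5, rel=1e-12)
        assert p == pytest.approx(1 - stats.f.cdf(13.5, 1, 4), rel=1e-9)

    def test_brute_force_sums_of_squares(self):
        rng = np.random.default_rng(6)
        a, b = rng.random(8), rng.random(5) + 0.2
        grand = np.concatenate([a, b]).mean()
        ssb = len(a) * (a.mean() - grand) ** 2 + len(b) * (b.mean() - grand) ** 2
        ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        f_oracle = (ssb / 1) / (ssw / (len(a) + len(b) - 2))
        f, _ = mx.anova_oneway(a, b)
        assert f == pytest.approx(f_oracle, rel=1e-10)

    def test_permutation_p_agreement(self):
        rng = np.random.default_rng(7)
        a, b = rng.random(10), rng.random(10) + 0.3
        f_obs, p = mx.anova_oneway(a, b)
        pooled = np.concatenate([a, b])
        count = 0
        n_perm = 2000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            f_perm, _ = mx.anova_oneway(perm[:10], perm[10:])
            count += f_perm >= f_obs
        p_perm = count / n_perm
        assert abs(p - p_perm) < 4 * np.sqrt(max(p_perm, 1 / n_perm) / n_perm) + 0.01

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            mx.anova_oneway([1.0], [2.0, 3.0])


class TestRound3:
    @pytest.mark.parametrize("x,expected", [
        (0.30064, 0.301), (0.9165, 0.917), (-0.0005, -0.001), (0.2175, 0.218),
    ])
    def test_half_away_from_zero(self, x, expected):
        assert mx.round3(x) == expected


class TestReportedCohort:
    def test_f1_consistent_for_all_coherent_rows(self):
        # published F1 equals the harmonic mean of the printed sensitivity
        # and precision within one unit of the printed precision, except for
        # three rows whose printed F1 is internally inconsistent (4, 25, 33)
        df = mx.load_reported_cohort()
        inconsistent = {4, 25, 33}
        for _, row in df.iterrows():
            re = mx.round3(mx.f1_measure(row["sensitivity"], row["precision"]))
            if row["subject"] in inconsistent:
                assert abs(re - row["f1"]) > 0.001 + 1e-12
            else:
                assert abs(re - row["f1"]) <= 0.001 + 1e-12, row["subject"]

    def test_table_structure(self):
        df = mx.load_reported_cohort()
        assert len(df) == 33
        assert set(df["group"]) == {"H", "L"}
        for col in ("accuracy", "sensitivity", "precision", "f1", "auc"):
            assert df[col].between(0, 1).all()
        assert (df["psnr_db"] < 0).all()
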