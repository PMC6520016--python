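import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from care_index.classifier_eval import (
    RocError,
    compare_aucs,
    contingency_metrics,
    optimal_threshold,
    ranking_table,
    roc_curve,
    transfer_threshold,
)


def pair_count_auc(scores, labels):
    """Exhaustive concordance probability with half-credit ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocCurve:
    def test_perfect_separation(self):
        curve = roc_curve([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert curve.auc == pytest.approx(1.0)
        j = curve.sensitivity + curve.specificity - 1
        assert j.max() == pytest.approx(1.0)

    def test_four_point_example(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        curve = roc_curve(scores, labels)
        assert curve.auc == pytest.approx(0.75)  # 3 of 4 pairs concordant

    def test_all_tied_scores_auc_half(self):
        curve = roc_curve([5.0] * 6, [0, 0, 0, 1, 1, 1])
        assert curve.auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(RocError):
            roc_curve([1.0, 2.0], [1, 1])

    def test_thresholds_strictly_increasing_with_sentinels(self):
        curve = roc_curve([3.0, 1.0, 2.0, 2.0], [0, 0, 1, 1])
        assert (np.diff(curve.thresholds) > 0).all()
        assert curve.thresholds[0] < 1.0 and curve.thresholds[-1] > 3.0

    def test_group_label_strings_accepted(self):
        curve = roc_curve([1.0, 5.0], ["N-MCI", "P-MCI"])
        assert curve.auc == pytest.approx(1.0)

    def test_auc_matches_sklearn_reference(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(5, 40))
            scores = np.round(rng.normal(size=n), 1)
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            assert roc_curve(scores, labels).auc == pytest.approx(
                roc_auc_score(labels, scores)
            )

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(st.integers(0, 9), min_size=2, max_size=30).filter(
            lambda s: len(s) >= 2
        ),
        st.data(),
    )
    def test_auc_equals_pair_counting(self, scores, data):
        labels = data.draw(
            st.lists(
                st.integers(0, 1), min_size=len(scores), max_size=len(scores)
            ).filter(lambda l: 0 < sum(l) < len(l))
        )
        curve = roc_curve(np.array(scores, float), labels)
        assert curve.auc == pytest.approx(pair_count_auc(scores, labels))


class TestOptimalThreshold:
    def test_perfect_separation_j_is_one(self):
        curve = roc_curve([1, 2, 8, 9], [0, 0, 1, 1])
        thr = optimal_threshold(curve)
        m = transfer_threshold(thr, [1, 2, 8, 9], [0, 0, 1, 1])
        assert m.sensitivity == 1.0 and m.specificity == 1.0

    def test_four_point_example_enumerated(self):
        # candidates enumerate to max J = 0.5 at sens 0.5 / spec 1.0
        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        thr = optimal_threshold(roc_curve(scores, labels))
        assert 0.4 < thr <= 0.8
        m = transfer_threshold(thr, scores, labels)
        assert m.sensitivity == pytest.approx(0.5)
        assert m.specificity == pytest.approx(1.0)

    def test_degenerate_all_ties_returns_j_zero_sentinel(self):
        curve = roc_curve([2.0] * 4, [0, 0, 1, 1])
        thr = optimal_threshold(curve)
        m = transfer_threshold(thr, [2.0] * 4, [0, 0, 1, 1])
        assert m.sensitivity + m.specificity - 1 == pytest.approx(0.0)

    def test_transfer_of_optimal_reproduces_curve_point(self):
        rng = np.random.default_rng(0)
        scores = np.round(rng.normal(size=40), 2)
        labels = (rng.random(40) < 0.4).astype(int)
        labels[:2] = [0, 1]
        curve = roc_curve(scores, labels)
        thr = optimal_threshold(curve)
        idx = int(np.flatnonzero(curve.thresholds == thr)[0])
        m = transfer_threshold(thr, scores, labels)
        assert m.sensitivity == pytest.approx(curve.sensitivity[idx])
        assert m.specificity == pytest.approx(curve.specificity[idx])


class TestContingencyMetrics:
    def test_discovery_cohort_row(self):
        m = contingency_metrics(9, 6, 3, 28)
        assert m.odds_ratio == pytest.approx(14.00, abs=0.005)
        assert m.or_ci[0] == pytest.approx(2.89, abs=0.01)
        assert m.or_ci[1] == pytest.approx(67.72, abs=0.01)
        assert m.relative_risk == pytest.approx(6.20, abs=0.005)
        assert m.rr_ci[0] == pytest.approx(1.96, abs=0.01)
        assert m.rr_ci[1] == pytest.approx(19.62, abs=0.01)
        assert 100 * m.accuracy == pytest.approx(80.43, abs=0.005)
        assert 100 * m.sensitivity == pytest.approx(75.0, abs=0.05)
        assert 100 * m.specificity == pytest.approx(82.4, abs=0.05)

    def test_validation_cohort_row(self):
        m = contingency_metrics(13, 5, 3, 35)
        assert m.odds_ratio == pytest.approx(30.33, abs=0.005)
        assert m.relative_risk == pytest.approx(9.15, abs=0.005)
        assert 100 * m.accuracy == pytest.approx(85.71, abs=0.005)
        assert 100 * m.sensitivity == pytest.approx(81.3, abs=0.05)
        assert 100 * m.specificity == pytest.approx(87.5, abs=0.05)

    def test_uniform_table_no_association(self):
        m = contingency_metrics(1, 1, 1, 1)
        assert m.odds_ratio == 1.0
        assert m.relative_risk == 1.0
        assert m.sensitivity == m.specificity == m.accuracy == 0.5

    def test_balanced_accuracy_identity(self):
        for counts in [(9, 6, 3, 28), (13, 5, 3, 35), (2, 7, 4, 1)]:
            m = contingency_metrics(*counts)
            assert m.balanced_accuracy == pytest.approx(
                (m.sensitivity + m.specificity) / 2
            )

    def test_odds_ratio_invariant_under_double_swap(self):
        m = contingency_metrics(9, 6, 3, 28)
        swapped = contingency_metrics(28, 3, 6, 9)  # swap rows and columns
        assert swapped.odds_ratio == pytest.approx(m.odds_ratio)

    def test_zero_cell_triggers_flagged_haldane(self):
        m = contingency_metrics(5, 0, 3, 7)
        assert m.haldane_correction
        assert math.isfinite(m.odds_ratio)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            contingency_metrics(-1, 2, 3, 4)


class TestTransferThreshold:
    def test_threshold_below_all_scores(self):
        m = transfer_threshold(-10.0, [1, 2, 3, 4], [0, 0, 1, 1])
        assert m.sensitivity == 1.0 and m.specificity == 0.0

    def test_threshold_above_all_scores(self):
        m = transfer_threshold(10.0, [1, 2, 3, 4], [0, 0, 1, 1])
        assert m.sensitivity == 0.0 and m.specificity == 1.0

    def test_constructed_validation_fixture_counts(self):
        """16 converters of whom 13 score above the transferred cutoff, 40
        stable of whom 5 do — the validation-cohort table shape."""
        thr = 6.54
        scores = np.concatenate(
            [np.full(13, 7.5), np.full(3, 5.0), np.full(5, 7.0), np.full(35, 4.0)]
        )
        labels = np.array([1] * 16 + [0] * 40)
        m = transfer_threshold(thr, scores, labels)
        assert (m.a, m.b, m.c, m.d) == (13, 5, 3, 35)
        assert m.odds_ratio == pytest.approx(30.33, abs=0.005)

    def test_nonfinite_threshold_rejected(self):
        with pytest.raises(ValueError):
            transfer_threshold(float("nan"), [1.0, 2.0], [0, 1])


class TestCompareAucs:
    def test_identical_scores_z_zero_p_one(self):
        s = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [0, 1, 0, 1, 0, 1]
        res = compare_aucs(s, s, y)
        assert res.z == 0.0 and res.p_value == 1.0

    def test_shifted_scores_equivalent(self):
        s = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = [0, 1, 0, 1, 0, 1]
        res = compare_aucs(s, s + 100.0, y)
        assert res.z == 0.0 and res.auc_a == pytest.approx(res.auc_b)

    def test_structural_components_match_bruteforce(self):
        sa = np.array([0.2, 0.9, 0.4, 0.7, 0.1, 0.6])
        sb = np.array([0.3, 0.5, 0.8, 0.2, 0.4, 0.9])
        y = np.array([0, 1, 0, 1, 0, 1])
        from care_index.classifier_eval import _placements

        pos, neg = sa[y == 1], sa[y == 0]
        v10, v01, auc = _placements(pos, neg)
        for i, p in enumerate(pos):
            manual = np.mean([1.0 if p > n else 0.5 if p == n else 0.0 for n in neg])
            assert v10[i] == pytest.approx(manual)
        for j, n in enumerate(neg):
            manual = np.mean([1.0 if p > n else 0.5 if p == n else 0.0 for p in pos])
            assert v01[j] == pytest.approx(manual)
        assert auc == pytest.approx(pair_count_auc(sa, y))

    def test_clearly_different_scores_significant(self):
        rng = np.random.default_rng(0)
        y = np.array([0] * 50 + [1] * 50)
        good = np.concatenate([rng.normal(0, 1, 50), rng.normal(3, 1, 50)])
        noise = rng.normal(size=100)
        res = compare_aucs(good, noise, y)
        assert res.p_value < 0.01

    def test_single_class_rejected(self):
        with pytest.raises(RocError):
            compare_aucs([1.0, 2.0], [2.0, 1.0], [1, 1])


class TestRankingTable:
    def test_two_predictors_ranked_by_auc(self):
        df = pd.DataFrame({"auc": [0.9, 0.7]}, index=["care", "mmse"])
        ranked = ranking_table(df)
        assert ranked.loc["care", "rank_auc"] == 1
        assert ranked.loc["mmse", "rank_auc"] == 2

    def test_ties_share_lower_rank(self):
        df = pd.DataFrame(
            {"accuracy": [0.8, 0.8, 0.7]}, index=["a", "b", "c"]
        )
        ranked = ranking_table(df)
        assert ranked["rank_accuracy"].tolist() == [1, 1, 3]

    def test_single_predictor_rejected(self):
        with pytest.raises(ValueError):
            ranking_table(pd.DataFrame({"auc": [0.9]}, index=["care"]))
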