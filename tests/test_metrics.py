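"""Evaluation metrics against independent oracles."""

import math
from fractions import Fraction

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score, roc_auc_score

import demrisk as d
from demrisk.metrics import ConfusionCounts, kappa_from_counts, round_half_up


def brute_force_auroc(scores, truth):
    """All-pairs concordance probability, ties counting one half."""
    s = np.asarray(scores, float)
    t = np.asarray(truth, int)
    pos, neg = s[t == 1], s[t == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def fraction_metrics(c: ConfusionCounts) -> dict:
    """Exact rational oracle for the confusion-table metrics."""
    n = Fraction(c.n)
    out = {"accuracy": Fraction(c.tp + c.tn) / n}
    if c.tp + c.fn:
        out["sensitivity"] = Fraction(c.tp, c.tp + c.fn)
    if c.tn + c.fp:
        out["specificity"] = Fraction(c.tn, c.tn + c.fp)
    if c.tp + c.fp:
        out["precision"] = Fraction(c.tp, c.tp + c.fp)
    if "sensitivity" in out and "precision" in out and (out["sensitivity"] + out["precision"]):
        out["f1"] = 2 * out["precision"] * out["sensitivity"] / (
            out["precision"] + out["sensitivity"])
    p_o = Fraction(c.tp + c.tn) / n
    p_e = (Fraction((c.tp + c.fn) * (c.tp + c.fp)) +
           Fraction((c.fp + c.tn) * (c.fn + c.tn))) / n**2
    if p_e != 1:
        out["kappa"] = (p_o - p_e) / (1 - p_e)
    elif p_o == 1:
        out["kappa"] = Fraction(1)
    return out


class TestConfusion:
    def test_perfect_agreement(self):
        c = d.confusion([1, 0, 1], [1, 0, 1])
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 1, 0, 0)

    def test_total_disagreement(self):
        c = d.confusion([0, 1, 0], [1, 0, 1])
        assert c.tp == 0 and c.tn == 0 and c.fp == 1 and c.fn == 2

    def test_empty_vectors_give_zero_counts(self):
        c = d.confusion([], [])
        assert c.n == 0

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            d.confusion([0, 2], [0, 1])


class TestMetricSet:
    def test_svm_row_confusion_table(self):
        # n=758 with 54 positives; tp=44, fp=24
        m = d.metric_set(ConfusionCounts(tp=44, fn=10, fp=24, tn=680))
        r = m.rounded()
        assert r["sensitivity"] == 0.81
        assert r["precision"] == 0.65
        assert r["specificity"] == 0.97
        assert r["accuracy"] == 0.96
        assert r["f1"] == 0.72
        assert r["kappa"] == 0.70

    def test_oracle_on_random_confusion_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            c = ConfusionCounts(*(int(v) for v in rng.integers(0, 40, size=4)))
            if c.n == 0:
                continue
            m = d.metric_set(c)
            oracle = fraction_metrics(c)
            for name in ("accuracy", "sensitivity", "specificity",
                         "precision", "f1", "kappa"):
                got = getattr(m, name)
                if name in oracle:
                    assert got == pytest.approx(float(oracle[name]), abs=1e-12), c
                else:
                    assert math.isnan(got) and name in m.undefined, c

    def test_perfect_prediction(self):
        m = d.evaluate_predictions([1, 0, 1, 0], [1, 0, 1, 0])
        assert m.accuracy == 1.0 and m.kappa == 1.0

    def test_constant_prediction_on_balanced_truth_has_zero_kappa(self):
        m = d.evaluate_predictions([1, 1, 1, 1], [1, 0, 1, 0])
        assert m.kappa == pytest.approx(0.0)

    def test_undefined_ratios_flagged_not_zeroed(self):
        m = d.metric_set(ConfusionCounts(tp=0, fn=3, fp=0, tn=5))
        assert math.isnan(m.precision) and "precision" in m.undefined

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            d.metric_set(ConfusionCounts(0, 0, 0, 0))

    def test_half_up_rounding(self):
        assert round_half_up(0.125, 2) == 0.13
        assert round_half_up(0.6449999, 2) == 0.64


class TestKappa:
    def test_symmetry_and_label_swap(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a = rng.integers(0, 2, size=30)
            b = rng.integers(0, 2, size=30)
            k_ab = kappa_from_counts(d.confusion(a, b))
            k_ba = kappa_from_counts(d.confusion(b, a))
            k_swap = kappa_from_counts(d.confusion(1 - a, 1 - b))
            assert k_ab == pytest.approx(k_ba, abs=1e-12)
            assert k_ab == pytest.approx(k_swap, abs=1e-12)
            assert kappa_from_counts(d.confusion(a, a)) == 1.0
            if len(set(a)) > 1 and len(set(b)) > 1:
                assert k_ab == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)


class TestAuroc:
    @pytest.mark.parametrize(
        "scores,truth,expected",
        [
            ([1, 2, 3, 4], [0, 0, 1, 1], 1.0),
            ([5, 5, 5, 5], [0, 1, 0, 1], 0.5),
            ([3, 1, 2, 4], [0, 0, 1, 1], 0.75),
        ],
    )
    def test_examples(self, scores, truth, expected):
        assert d.auroc(scores, truth) == pytest.approx(expected)

    def test_matches_all_pairs_concordance_with_ties(self):
        rng = np.random.default_rng(11)
        for n in (10, 57, 200, 500):
            s = rng.integers(0, 15, size=n).astype(float)  # heavy ties
            y = (rng.random(n) < 0.3).astype(int)
            if y.sum() in (0, n):
                continue
            assert d.auroc(s, y) == pytest.approx(brute_force_auroc(s, y), abs=1e-12)
            assert d.auroc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            d.auroc([1, 2], [1, 1])


class TestCompareToRaters:
    def test_zero_variance_panel_is_degenerate(self):
        consensus = [1, 0, 1, 0, 0]
        raters = [consensus, consensus, consensus]
        cmp = d.compare_to_raters(raters, consensus, consensus)
        assert cmp.degenerate
        assert math.isnan(cmp.accuracy_p)

    def test_hand_computed_t_test_on_five_case_fixture(self):
        consensus = [1, 0, 1, 0, 0]
        raters = [
            [1, 0, 1, 0, 1],  # accuracy 0.8
            [1, 0, 1, 0, 0],  # accuracy 1.0
            [0, 0, 1, 0, 0],  # accuracy 0.8
        ]
        model = [1, 0, 0, 0, 0]  # accuracy 0.8
        cmp = d.compare_to_raters(raters, consensus, model)
        assert cmp.rater_accuracy_mean == pytest.approx(13 / 15)
        # t = (mean - 0.8) / (sd / sqrt(3)) = 1; df=2 -> p = 1 - 1/sqrt(3)
        assert cmp.accuracy_p == pytest.approx(1 - 1 / math.sqrt(3), abs=1e-9)
        lo, hi = cmp.rater_accuracy_ci
        assert lo < cmp.rater_accuracy_mean < hi

    def test_raters_centered_on_model_give_large_p(self):
        consensus = [1, 1, 0, 0, 1, 0, 1, 0, 1, 0]
        model = [1, 1, 0, 0, 1, 0, 1, 0, 0, 0]      # accuracy 0.9
        raters = [
            [1, 1, 0, 0, 1, 0, 1, 0, 0, 1],          # 0.8
            [1, 1, 0, 0, 1, 0, 1, 0, 1, 0],          # 1.0
            [1, 1, 0, 1, 1, 0, 1, 0, 1, 0],          # 0.9
            [1, 1, 0, 0, 0, 0, 1, 0, 1, 0],          # 0.9
        ]
        # rater accuracies are symmetric around the model's 0.9 -> t = 0
        cmp = d.compare_to_raters(raters, consensus, model)
        assert cmp.accuracy_p > 0.99

    def test_fewer_than_two_raters_rejected(self):
        with pytest.raises(ValueError):
            d.compare_to_raters([[1, 0]], [1, 0], [1, 0])


def test_svm_row_reconstruction_is_unique():
    """Only one 2x2 table with n=758 and 54 positives matches the printed
    sensitivity .81 and precision .65 after half-up rounding."""
    matches = []
    for tp in range(55):
        if round_half_up(tp / 54) != 0.81:
            continue
        for fp in range(705):
            if tp + fp and round_half_up(tp / (tp + fp)) == 0.65:
                matches.append(ConfusionCounts(tp, 54 - tp, fp, 704 - fp))
    assert len(matches) == 1
    assert (matches[0].tp, matches[0].fp) == (44, 24)
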