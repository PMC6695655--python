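"""The 28-metric panel: worked examples, identities, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_confusion, random_predictions
from srdeval.metrics import (
    PANEL,
    PANEL_ABBREVIATIONS,
    SMALLER_BETTER,
    ScoredPredictions,
    _multiclass_composites,
    brier_score,
    composite_local_metrics,
    confusion_matrix,
    curve_metrics,
    enrichment_metrics,
    evaluate_panel,
    labels_from_probabilities,
    one_sided_rates,
    one_vs_rest_weighted,
    rie_bedroc,
)


class TestLabelsFromProbabilities:
    def test_argmax_and_tie_toward_lowest_code(self):
        preds = ScoredPredictions(
            np.array([[0.1, 0.7, 0.2], [0.5, 0.2, 0.3], [1 / 3, 1 / 3, 1 / 3]]),
            np.array([1, 1, 1]),
        )
        assert labels_from_probabilities(preds).tolist() == [2, 1, 1]

    def test_two_way_tie(self):
        preds = ScoredPredictions(np.array([[0.5, 0.5]]), np.array([2]))
        assert labels_from_probabilities(preds).tolist() == [1]

    def test_one_hot_recovers_truth(self, rng):
        y = rng.integers(1, 4, size=30)
        probs = np.zeros((30, 3))
        probs[np.arange(30), y - 1] = 1.0
        preds = ScoredPredictions(probs, y)
        assert np.array_equal(labels_from_probabilities(preds), y)


class TestConfusionMatrix:
    def test_direct_counts(self):
        cm = confusion_matrix([1, 1, 2, 2], [1, 2, 2, 2], k=2)
        assert cm.binary(1) == (1, 1, 0, 2)

    def test_perfect_prediction_diagonal(self, rng):
        y = rng.integers(1, 5, size=40)
        cm = confusion_matrix(y, y, k=4)
        assert np.all(cm.counts == np.diag(np.diag(cm.counts)))

    def test_empty_and_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([], [], k=2)
        with pytest.raises(ValueError):
            confusion_matrix([1, 3], [1, 1], k=2)


class TestOneSidedRates:
    def test_worked_example(self):
        r = one_sided_rates(40, 10, 20, 30)
        assert r["TPR"] == pytest.approx(0.8)
        assert r["TNR"] == pytest.approx(0.6)
        assert r["PPV"] == pytest.approx(2 / 3)
        assert r["NPV"] == pytest.approx(0.75)

    def test_perfect_classifier(self):
        r = one_sided_rates(10, 0, 0, 15)
        assert [r["TPR"], r["TNR"], r["PPV"], r["NPV"]] == [1, 1, 1, 1]
        assert [r["FNR"], r["FPR"], r["FDR"], r["FOR"]] == [0, 0, 0, 0]

    def test_zero_denominator_marks_pair_undefined(self):
        r = one_sided_rates(5, 5, 0, 0)  # N = 0
        assert math.isnan(r["TNR"]) and math.isnan(r["FPR"])

    @settings(derandomize=True, max_examples=200)
    @given(st.tuples(*[st.integers(1, 50)] * 4))
    def test_complement_identities(self, cells):
        r = one_sided_rates(*cells)
        for a, b in (("TPR", "FNR"), ("TNR", "FPR"), ("PPV", "FDR"), ("NPV", "FOR")):
            assert r[a] + r[b] == pytest.approx(1.0, abs=1e-12)


class TestCompositeMetrics:
    def test_worked_example(self):
        c = composite_local_metrics(40, 10, 20, 30)
        assert c["ACC"] == pytest.approx(0.7)
        assert c["BACC"] == pytest.approx(0.7)
        assert c["F1"] == pytest.approx(8 / 11)
        assert c["MCC"] == pytest.approx(1000 / math.sqrt(6_000_000))
        assert c["BM"] == pytest.approx(0.4)
        assert c["MK"] == pytest.approx(0.25 / 0.6)
        assert c["LR+"] == pytest.approx(2.0)
        assert c["LR-"] == pytest.approx(1 / 3)
        assert c["DOR"] == pytest.approx(6.0)
        assert c["kappa"] == pytest.approx(0.4)
        assert c["J"] == pytest.approx(4 / 7)

    def test_perfect_classifier_infinite_dor(self):
        c = composite_local_metrics(10, 0, 0, 15)
        for name in ("ACC", "BACC", "F1", "MCC", "kappa", "J", "BM", "MK"):
            assert c[name] == pytest.approx(1.0)
        assert math.isinf(c["DOR"]) and c["DOR"] > 0

    def test_all_predicted_positive(self):
        c = composite_local_metrics(10, 0, 20, 0)
        assert c["BM"] == pytest.approx(0.0)
        assert c["kappa"] == pytest.approx(0.0)

    def test_continuity_correction_is_finite(self):
        c = composite_local_metrics(10, 0, 0, 15, continuity_correction=True)
        assert math.isfinite(c["DOR"]) and c["DOR"] > 1

    def test_identities_on_random_tables(self, rng):
        for _ in range(1000):
            tp, fn, fp, tn = random_confusion(rng)
            r = one_sided_rates(tp, fn, fp, tn)
            c = composite_local_metrics(tp, fn, fp, tn)
            assert c["BACC"] == pytest.approx((r["TPR"] + r["TNR"]) / 2, abs=1e-12)
            assert c["BM"] == pytest.approx(r["TPR"] + r["TNR"] - 1, abs=1e-12)
            if not math.isnan(c["MK"]):
                assert c["MK"] == pytest.approx(r["PPV"] + r["NPV"] - 1, abs=1e-12)
            if fp > 0 and fn > 0:
                assert c["DOR"] == pytest.approx(c["LR+"] / c["LR-"], rel=1e-12)
                assert c["DOR"] == pytest.approx(tp * tn / (fp * fn), rel=1e-12)

    def test_multiclass_forms_reduce_to_binary_at_k2(self, rng):
        for _ in range(500):
            tp, fn, fp, tn = random_confusion(rng)
            cm = confusion_matrix(
                [2] * (tp + fn) + [1] * (fp + tn),
                [2] * tp + [1] * fn + [2] * fp + [1] * tn,
                k=2,
            )
            multi = _multiclass_composites(cm)
            binary = composite_local_metrics(tp, fn, fp, tn)
            for name in ("ACC", "MCC", "kappa"):
                assert multi[name] == pytest.approx(binary[name], abs=1e-12)


class TestBrierScore:
    def test_examples(self):
        perfect = ScoredPredictions(np.array([[1.0, 0.0], [0.0, 1.0]]), np.array([1, 2]))
        assert brier_score(perfect) == 0.0
        single = ScoredPredictions(np.array([[0.8, 0.2]]), np.array([1]))
        assert brier_score(single) == pytest.approx(0.08)
        uniform = ScoredPredictions(np.full((5, 2), 0.5), np.array([1, 2, 1, 2, 1]))
        assert brier_score(uniform) == pytest.approx(0.5)

    def test_row_sum_validated(self):
        with pytest.raises(ValueError):
            ScoredPredictions(np.array([[0.7, 0.2]]), np.array([1]))


class TestEnrichment:
    def test_top_fraction_all_positive(self):
        scores = np.linspace(1, 0, 100)
        labels = np.zeros(100, bool)
        labels[:5] = True
        labels[50:55] = True  # P = 10, top five all positive
        ef, _ = enrichment_metrics(scores, labels, x=5)
        assert ef == pytest.approx((5 / 5) / (10 / 100))

    def test_roc_enrichment_through_known_point(self):
        # ROC flat segment through (FPR=0.05, TPR=0.5): P=2, N=20
        scores = np.concatenate([[0.9, 0.8, 0.7, 0.6], np.linspace(0.5, 0.1, 18)])
        labels = np.zeros(22, bool)
        labels[0] = labels[3] = True
        _, roc_ef = enrichment_metrics(scores, labels, x=5)
        assert roc_ef == pytest.approx(0.5 / 0.05)

    def test_random_scores_give_unit_enrichment(self, rng):
        efs = []
        for _ in range(40):
            scores = rng.random(400)
            labels = rng.random(400) < 0.25
            if labels.any() and not labels.all():
                efs.append(enrichment_metrics(scores, labels, x=5)[0])
        assert np.mean(efs) == pytest.approx(1.0, abs=0.15)

    def test_all_one_class_rejected(self):
        with pytest.raises(ValueError):
            enrichment_metrics([0.1, 0.9], [True, True], x=5)


class TestRieBedroc:
    def test_extreme_orderings(self):
        scores = np.linspace(1, 0, 20)
        first = np.zeros(20, bool)
        first[:4] = True
        last = np.zeros(20, bool)
        last[-4:] = True
        assert rie_bedroc(scores, first)[1] == pytest.approx(1.0)
        assert rie_bedroc(scores, last)[1] == pytest.approx(0.0)

    def test_uniform_positives_give_unit_rie(self):
        n = 1000
        scores = np.linspace(1, 0, n)
        labels = np.zeros(n, bool)
        labels[np.arange(5, n, 10)] = True  # evenly spread positives
        rie, _ = rie_bedroc(scores, labels, alpha=20)
        assert rie == pytest.approx(1.0, abs=0.05)

    def test_bedroc_bounded(self, rng):
        for _ in range(50):
            scores = rng.random(30)
            labels = rng.random(30) < 0.4
            if labels.any() and not labels.all():
                _, bedroc = rie_bedroc(scores, labels)
                assert 0 <= bedroc <= 1


class TestCurveMetrics:
    def test_pair_counting_example(self):
        out = curve_metrics([0.9, 0.8, 0.7, 0.6], [True, False, True, False])
        assert out["AUC"] == pytest.approx(0.75)

    def test_perfect_ranking(self):
        out = curve_metrics([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        assert out["AUC"] == 1.0
        assert out["AP"] == 1.0
        assert out["r"] == pytest.approx(3 / 8)  # positives at ranks 1 and 2 of 4

    def test_bounds_on_random_vectors(self, rng):
        for _ in range(100):
            scores = rng.integers(0, 5, size=25) / 4  # heavy ties
            labels = rng.random(25) < 0.5
            if labels.any() and not labels.all():
                out = curve_metrics(scores, labels)
                for name in ("AUC", "AUAC", "AP"):
                    assert 0 <= out[name] <= 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            curve_metrics([0.2, 0.4], [False, False])


class TestOneVsRest:
    def test_k2_balanced_tpr_equals_bacc(self, rng):
        preds = random_predictions(rng, n=80, k=2)
        predicted = labels_from_probabilities(preds)
        counts = np.bincount(preds.true_labels, minlength=3)[1:]
        tpr = one_vs_rest_weighted(
            lambda s, m, tp, fn, fp, tn: one_sided_rates(tp, fn, fp, tn)["TPR"], preds
        )
        cm = confusion_matrix(preds.true_labels, predicted, 2)
        tp, fn, fp, tn = cm.binary(2)
        c = composite_local_metrics(tp, fn, fp, tn)
        if counts[0] == counts[1]:
            assert tpr == pytest.approx(c["BACC"])
        else:  # weighted mean of per-class recalls, not BACC, in general
            per_class = [one_sided_rates(*cm.binary(j))["TPR"] for j in (1, 2)]
            assert tpr == pytest.approx(np.average(per_class, weights=counts))

    def test_weighted_average_arithmetic(self):
        # per-class metric values (1, 0, 1) with counts (2, 3, 5) -> 0.7
        values = {1: 1.0, 2: 0.0, 3: 1.0}
        counts = {1: 2, 2: 3, 3: 5}
        y = np.concatenate([[c] * n for c, n in counts.items()])
        probs = np.zeros((10, 3))
        probs[np.arange(10), y - 1] = 1.0
        preds = ScoredPredictions(probs, y)

        def metric(scores, mask, *cells):
            return values[int(y[mask][0])]

        assert one_vs_rest_weighted(metric, preds) == pytest.approx(0.7)

    def test_perfect_multiclass_f1(self, rng):
        y = rng.integers(1, 4, size=30)
        probs = np.zeros((30, 3))
        probs[np.arange(30), y - 1] = 1.0
        f1 = one_vs_rest_weighted(
            lambda s, m, tp, fn, fp, tn: composite_local_metrics(tp, fn, fp, tn)["F1"],
            ScoredPredictions(probs, y),
        )
        assert f1 == pytest.approx(1.0)


class TestEvaluatePanel:
    def test_record_length_and_order(self, rng):
        panel = evaluate_panel(random_predictions(rng, n=60, k=2))
        assert list(panel.index) == PANEL_ABBREVIATIONS
        assert len(panel) == 28

    def test_multiclass_record_complete(self, rng):
        panel = evaluate_panel(random_predictions(rng, n=90, k=4))
        assert len(panel) == 28
        assert panel.notna().all()

    def test_perfect_two_class(self, rng):
        y = rng.integers(1, 3, size=40)
        probs = np.zeros((40, 2))
        probs[np.arange(40), y - 1] = 1.0
        panel = evaluate_panel(ScoredPredictions(probs, y))
        for abbr in ("TPR", "TNR", "PPV", "NPV", "ACC", "BACC", "F1", "MCC",
                     "kappa", "J", "AUC", "AP", "BEDROC"):
            assert panel[abbr] == pytest.approx(1.0)
        assert panel["B"] == 0.0
        # minimal average rank: positives occupy the top of the list
        p = int((y == 2).sum())
        assert panel["r"] == pytest.approx((p + 1) / (2 * 40))

    def test_deterministic(self, rng):
        preds = random_predictions(rng, n=50, k=3)
        a = evaluate_panel(preds)
        b = evaluate_panel(preds)
        assert a.equals(b)

    def test_sample_permutation_invariance(self, rng):
        preds = random_predictions(rng, n=70, k=2)
        perm = rng.permutation(70)
        shuffled = ScoredPredictions(preds.probabilities[perm], preds.true_labels[perm])
        a, b = evaluate_panel(preds), evaluate_panel(shuffled)
        assert np.allclose(a.to_numpy(), b.to_numpy(), equal_nan=True)

    def test_panel_metadata(self):
        assert sum(d.family == "local-one-sided" for d in PANEL) == 8
        assert sum(d.family == "global" for d in PANEL) == 5
        assert {d.abbreviation for d in PANEL if not d.greater_is_better} == set(SMALLER_BETTER)
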