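"""Confusion-matrix metrics, AUC rank statistic, aggregation, and the
integer confusion-count recovery used to verify printed metric tables."""

import math
from fractions import Fraction
from itertools import product

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dbtmc.evaluation import (
    ConfusionMatrix,
    PredictionRecord,
    aggregate_lesion_level,
    confusion_from_predictions,
    evaluate_predictions,
    metrics_from_confusion,
    recover_confusion_counts,
    roc_auc,
)

# Published metric rows (model, AUC omitted): SEN%, SPEC%, ACC%, Precision%, F1%
# on a test composition of 32 malignant + 18 benign samples.
PRINTED_ROWS = {
    "2D-ResNet18": (81.25, 61.11, 74.00, 78.79, 80.00),
    "2D-ResNet34": (78.13, 72.22, 76.00, 83.33, 80.65),
    "2D-ResNet50": (75.00, 66.67, 72.00, 80.00, 77.42),
    "3D-ResNet-Isotropic": (87.50, 61.11, 78.00, 80.00, 83.58),
    "3D-ResNet-Anisotropic": (75.00, 77.78, 76.00, 85.71, 80.00),
    "Feature-Ensemble": (87.50, 55.56, 76.00, 77.78, 82.35),
    "Decision-Ensemble-UA": (84.38, 77.78, 82.00, 87.10, 85.71),
    "Decision-Ensemble-WA(0.3)": (81.25, 77.78, 80.00, 86.67, 83.87),
    "Decision-Ensemble-WA(0.7)": (75.00, 72.22, 74.00, 82.76, 78.69),
    "Radiomics-2D-domain": (87.50, 55.56, 76.00, 77.78, 82.35),
    "Radiomics-3D-domain": (78.13, 66.67, 74.00, 80.65, 79.37),
    "Radiomics-Combined": (81.25, 55.56, 72.00, 76.47, 78.79),
}
N_POS, N_NEG = 32, 18


def _preds(scores, labels):
    return [
        PredictionRecord(lesion_id=f"L{i}", view="CC", label=int(l),
                         p_malignant=float(s))
        for i, (s, l) in enumerate(zip(scores, labels))
    ]


class TestConfusion:
    def test_all_correct_confident(self):
        cm = confusion_from_predictions(_preds([0.9, 0.9, 0.1], [1, 1, 0]))
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (2, 0, 0, 1)

    def test_score_at_threshold_counts_positive(self):
        cm = confusion_from_predictions(_preds([0.5, 0.5], [1, 0]))
        assert cm.tp == 1 and cm.fp == 1

    def test_mixed_counts(self):
        # 32 positives / 18 negatives, 27 and 14 of them called correctly
        labels = [1] * 32 + [0] * 18
        scores = [0.9] * 27 + [0.1] * 5 + [0.9] * 4 + [0.1] * 14
        cm = confusion_from_predictions(_preds(scores, labels))
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (27, 5, 4, 14)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            confusion_from_predictions([])

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, fn=0, fp=0, tn=0)


class TestMetrics:
    def test_decision_ua_row(self):
        m = metrics_from_confusion(ConfusionMatrix(27, 5, 4, 14))
        assert round(m.acc, 4) == 0.8200
        assert round(m.sen, 4) == 0.8438
        assert round(m.spec, 4) == 0.7778
        assert round(m.precision, 4) == 0.8710
        assert round(m.f1, 4) == 0.8571

    def test_isotropic_row(self):
        m = metrics_from_confusion(ConfusionMatrix(28, 4, 7, 11))
        assert math.isclose(m.acc, 0.78)
        assert math.isclose(m.precision, 0.80)
        assert round(m.f1, 4) == 0.8358

    def test_perfect_classifier(self):
        m = metrics_from_confusion(ConfusionMatrix(1, 0, 0, 1))
        assert m.acc == m.sen == m.spec == m.precision == m.f1 == 1.0

    def test_recall_equals_sensitivity(self):
        m = metrics_from_confusion(ConfusionMatrix(5, 3, 2, 7))
        assert m.recall == m.sen

    def test_undefined_precision_is_nan_not_zero(self):
        m = metrics_from_confusion(ConfusionMatrix(0, 3, 0, 5))
        assert math.isnan(m.precision) and math.isnan(m.f1)

    def test_all_zero_matrix_errors(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(ConfusionMatrix(0, 0, 0, 0))


def _pairwise_auc(scores, labels):
    """Independent oracle: exhaustive positive/negative pair comparison."""
    pos = [Fraction(s).limit_denominator() for s, l in zip(scores, labels) if l == 1]
    neg = [Fraction(s).limit_denominator() for s, l in zip(scores, labels) if l == 0]
    total = Fraction(0)
    for p in pos:
        for q in neg:
            if p > q:
                total += 1
            elif p == q:
                total += Fraction(1, 2)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(10_000)
        labels = rng.integers(0, 2, 10_000)
        assert abs(roc_auc(scores, labels) - 0.5) < 0.02

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_matches_pairwise_oracle_exhaustively(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(2, 13))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = rng.integers(0, 5, n) / 4.0  # coarse grid forces ties
            expected = _pairwise_auc(scores.tolist(), labels.tolist())
            assert Fraction(roc_auc(scores, labels)).limit_denominator(10**6) == expected


class TestLesionAggregation:
    def test_two_views_average(self):
        recs = [
            PredictionRecord("L1", "CC", 1, 0.6),
            PredictionRecord("L1", "MLO", 1, 0.8),
        ]
        (out,) = aggregate_lesion_level(recs)
        assert out.p_malignant == pytest.approx(0.7)
        assert out.label == 1

    def test_single_view_identity(self):
        recs = [PredictionRecord("L1", "CC", 0, 0.3)]
        (out,) = aggregate_lesion_level(recs)
        assert out.p_malignant == 0.3

    def test_cardinality_halves(self):
        recs = [
            PredictionRecord(f"L{i}", v, i % 2, 0.5)
            for i in range(4)
            for v in ("CC", "MLO")
        ]
        assert len(aggregate_lesion_level(recs)) == 4

    def test_conflicting_labels_error(self):
        recs = [
            PredictionRecord("L1", "CC", 1, 0.6),
            PredictionRecord("L1", "MLO", 0, 0.8),
        ]
        with pytest.raises(ValueError):
            aggregate_lesion_level(recs)

    def test_duplicated_identical_views_keep_auc(self):
        rng = np.random.default_rng(3)
        scores = rng.random(20)
        labels = np.r_[np.ones(10, int), np.zeros(10, int)]
        view = [
            PredictionRecord(f"L{i}", v, int(labels[i]), float(scores[i]))
            for i in range(20)
            for v in ("CC", "MLO")
        ]
        lesion = aggregate_lesion_level(view)
        assert roc_auc([r.p_malignant for r in lesion], [r.label for r in lesion]) == (
            pytest.approx(roc_auc(scores, labels))
        )


class TestRecovery:
    @pytest.mark.parametrize(
        "sen,spec,expected",
        [
            (84.38, 77.78, (27, 5, 4, 14)),
            (78.13, 72.22, (25, 7, 5, 13)),
            (100.0, 100.0, (32, 0, 0, 18)),
        ],
    )
    def test_known_counts(self, sen, spec, expected):
        cm = recover_confusion_counts(sen, spec, N_POS, N_NEG)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == expected

    def test_impossible_percentages_error(self):
        with pytest.raises(ValueError):
            recover_confusion_counts(84.00, 77.78, N_POS, N_NEG)

    def test_bad_composition_errors(self):
        with pytest.raises(ValueError):
            recover_confusion_counts(50.0, 50.0, 0, 18)

    @pytest.mark.parametrize("model", sorted(PRINTED_ROWS))
    def test_round_trip_reproduces_printed_tables(self, model):
        """Recovered integer counts must reproduce every printed ACC,
        Precision and F1 to two decimals from that row's SEN/SPEC alone."""
        sen, spec, acc, precision, f1 = PRINTED_ROWS[model]
        cm = recover_confusion_counts(sen, spec, N_POS, N_NEG)
        m = metrics_from_confusion(cm)
        assert round(100 * m.acc, 2) == acc
        assert round(100 * m.precision, 2) == precision
        assert round(100 * m.f1, 2) == f1


class TestEvaluatePredictions:
    def test_view_and_lesion_reports(self):
        recs = []
        rng = np.random.default_rng(5)
        for i in range(12):
            label = i % 2
            base = 0.75 if label else 0.25
            for v in ("CC", "MLO"):
                recs.append(
                    PredictionRecord(f"L{i}", v, label,
                                     float(np.clip(base + rng.normal(0, 0.1), 0, 1)))
                )
        view = evaluate_predictions(recs, level="view")
        lesion = evaluate_predictions(recs, level="lesion")
        assert view.n_pos + view.n_neg == 24
        assert lesion.n_pos + lesion.n_neg == 12
        assert 0.0 <= lesion.auc <= 1.0

    def test_unknown_level_errors(self):
        with pytest.raises(ValueError):
            evaluate_predictions(_preds([0.5], [1]), level="patient")


@given(st.lists(st.tuples(st.floats(0, 1), st.integers(0, 1)), min_size=4,
                max_size=30))
def test_confusion_partitions_samples(pairs):
    labels = [l for _, l in pairs]
    if len(set(labels)) < 2:
        pairs = pairs + [(0.5, 0), (0.5, 1)]
    preds = _preds([s for s, _ in pairs], [l for _, l in pairs])
    cm = confusion_from_predictions(preds)
    assert cm.tp + cm.fn == sum(1 for p in preds if p.label == 1)
    assert cm.fp + cm.tn == sum(1 for p in preds if p.label == 0)
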