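import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

import table_data as td
from histotune.metrics import (
    ConfusionCounts,
    MetricReport,
    UndefinedMetricError,
    aggregate_reports,
    auc_rank,
    compute_metrics,
    cosine_similarity_score,
    micro_confusion,
    report_frame,
    round_half_up,
    weighted_sum,
)


def binary_counts(tp, fp):
    return ConfusionCounts(TP=tp, TN=tp, FP=fp, FN=fp)


class TestMicroConfusion:
    def test_perfect_binary(self):
        y = np.array([0, 1] * 10)
        c = micro_confusion(y, y, 2)
        assert (c.TP, c.TN, c.FP, c.FN) == (20, 20, 0, 0)

    def test_binary_symmetry(self, rng):
        y = rng.integers(0, 2, 50)
        p = rng.integers(0, 2, 50)
        c = micro_confusion(y, p, 2)
        assert c.TP == c.TN and c.FP == c.FN

    def test_three_class_against_manual_sums(self):
        y = [0, 0, 0, 1, 1, 1, 2, 2, 2]
        p = [0, 1, 2, 1, 1, 0, 2, 2, 1]
        c = micro_confusion(y, p, 3)
        # brute-force one-vs-rest sums over the 3x3 confusion table
        tp = fp = fn = tn = 0
        for k in range(3):
            for yi, pi in zip(y, p):
                if yi == k and pi == k:
                    tp += 1
                elif yi != k and pi == k:
                    fp += 1
                elif yi == k and pi != k:
                    fn += 1
                else:
                    tn += 1
        assert (c.TP, c.TN, c.FP, c.FN) == (tp, tn, fp, fn)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            micro_confusion([0, 1], [0], 2)


class TestComputeMetrics:
    def test_published_counts_reproduce_printed_accuracy(self):
        rep = compute_metrics(binary_counts(5351, 25))
        assert round_half_up(rep.accuracy) == 99.53

    def test_published_counts_reproduce_printed_youden(self):
        rep = compute_metrics(binary_counts(5359, 17))
        assert round_half_up(rep.youden_index) == 99.37

    @pytest.mark.parametrize("tp,fp,acc,youden", list(zip(td.AO_TP, td.AO_FP, td.AO_ACCURACY, td.AO_YOUDEN)))
    def test_all_aquila_columns(self, tp, fp, acc, youden):
        rep = compute_metrics(binary_counts(tp, fp))
        for metric in ("accuracy", "f1", "precision", "recall", "specificity", "npv"):
            assert round_half_up(getattr(rep, metric)) == acc
        assert round_half_up(rep.youden_index) == youden

    @pytest.mark.parametrize("tp,fp,acc,youden", list(zip(td.GTO_TP, td.GTO_FP, td.GTO_ACCURACY, td.GTO_YOUDEN)))
    def test_all_gorilla_columns(self, tp, fp, acc, youden):
        rep = compute_metrics(binary_counts(tp, fp))
        for metric in ("accuracy", "f1", "precision", "recall", "specificity", "npv"):
            assert round_half_up(getattr(rep, metric)) == acc
        assert round_half_up(rep.youden_index) == youden

    def test_single_true_positive(self):
        rep = compute_metrics(ConfusionCounts(TP=1, TN=1, FP=0, FN=0))
        assert rep.accuracy == rep.precision == rep.recall == 100.0
        assert rep.youden_index == 100.0

    def test_sensitivity_equals_recall(self, rng):
        rep = compute_metrics(binary_counts(int(rng.integers(1, 100)), int(rng.integers(0, 50))))
        assert rep.sensitivity == rep.recall

    def test_zero_denominator_is_undefined_not_fatal(self):
        rep = compute_metrics(ConfusionCounts(TP=0, TN=5, FP=0, FN=0))
        assert rep.precision is None
        assert rep.accuracy == 100.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(0, 10_000))
    def test_dice_iou_identity(self, tp, fp):
        rep = compute_metrics(binary_counts(max(tp, 1), fp))
        dice, iou = rep.dice / 100.0, rep.iou / 100.0
        assert dice == pytest.approx(2 * iou / (1 + iou))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(1, 10_000), st.integers(0, 10_000))
    def test_youden_identity(self, tp, fp):
        rep = compute_metrics(binary_counts(tp, fp))
        assert rep.youden_index == pytest.approx(rep.sensitivity + rep.specificity - 100.0)

    def test_micro_binary_metric_equalities(self, rng):
        # with TP=TN and FP=FN, the six ratio metrics coincide exactly
        rep = compute_metrics(binary_counts(4779, 617))
        vals = {rep.accuracy, rep.f1, rep.precision, rep.recall, rep.specificity, rep.npv}
        assert len(vals) == 1


class TestAuc:
    def test_perfect_separation(self):
        assert auc_rank([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 100.0

    def test_inverted_scores(self):
        assert auc_rank([0, 0, 1, 1], [0.9, 0.8, 0.2, 0.1]) == 0.0

    def test_null_distribution(self, rng):
        y = rng.integers(0, 2, 1000)
        s = rng.random(1000)
        assert auc_rank(y, s) == pytest.approx(50.0, abs=3.0)

    def test_matches_reference_implementation(self, rng):
        y = rng.integers(0, 2, 200)
        s = rng.random(200)
        s[::7] = 0.5  # inject ties
        assert auc_rank(y, s) == pytest.approx(100.0 * roc_auc_score(y, s), abs=1e-9)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auc_rank([1, 1, 1], [0.1, 0.2, 0.3])


class TestCosine:
    def test_identical_predictions(self):
        y = np.eye(2)[[0, 1, 0]]
        assert cosine_similarity_score(y, y) == pytest.approx(100.0)

    def test_uniform_binary_predictions(self):
        y = np.eye(2)[[0, 1, 1, 0]]
        p = np.full((4, 2), 0.5)
        assert cosine_similarity_score(y, p) == pytest.approx(100.0 / np.sqrt(2), abs=1e-9)

    def test_orthogonal_prediction(self):
        y = np.array([[1.0, 0.0]])
        p = np.array([[0.0, 1.0]])
        assert cosine_similarity_score(y, p) == 0.0

    def test_zero_norm_row(self):
        with pytest.raises(UndefinedMetricError):
            cosine_similarity_score(np.array([[1.0, 0.0]]), np.array([[0.0, 0.0]]))


def full_report(v):
    return MetricReport(**{name: v for name in MetricReport().to_dict()})


class TestWeightedSum:
    def test_fixed_point(self):
        assert weighted_sum(full_report(93.4)) == pytest.approx(93.4)

    def test_linearity(self):
        base = full_report(80.0)
        bumped = MetricReport(**{**base.to_dict(), "iou": 92.0})
        assert weighted_sum(bumped) - weighted_sum(base) == pytest.approx(1.0)

    def test_published_column_mean(self):
        # the Aquila Xception column: mean of its 12 printed entries
        vals = dict(
            accuracy=99.53, f1=99.53, precision=99.53, recall=99.53, specificity=99.53,
            auc=99.95, sensitivity=99.53, iou=99.44, dice=99.54, cosine_similarity=99.61,
            youden_index=99.07, npv=99.53,
        )
        assert weighted_sum(MetricReport(**vals)) == pytest.approx(np.mean(list(vals.values())))

    def test_undefined_component(self):
        with pytest.raises(UndefinedMetricError):
            weighted_sum(MetricReport(accuracy=90.0))


class TestAggregation:
    def test_aquila_suite_average_accuracy(self):
        reports = [compute_metrics(binary_counts(tp, fp)) for tp, fp in zip(td.AO_TP, td.AO_FP)]
        agg = aggregate_reports(reports)
        assert round_half_up(agg.accuracy) == td.AO_MEAN_ACCURACY
        assert round_half_up(agg.youden_index) == td.AO_MEAN_YOUDEN

    def test_gorilla_suite_average_accuracy(self):
        reports = [compute_metrics(binary_counts(tp, fp)) for tp, fp in zip(td.GTO_TP, td.GTO_FP)]
        agg = aggregate_reports(reports)
        assert round_half_up(agg.accuracy) == td.GTO_MEAN_ACCURACY
        assert round_half_up(agg.youden_index) == td.GTO_MEAN_YOUDEN

    def test_printed_auc_rows_average(self):
        assert round_half_up(np.mean(td.AO_AUC)) == td.AO_MEAN_AUC
        assert round_half_up(np.mean(td.GTO_AUC)) == td.GTO_MEAN_AUC

    def test_single_report_identity(self):
        rep = compute_metrics(binary_counts(10, 3))
        agg = aggregate_reports([rep])
        assert agg.accuracy == rep.accuracy and agg.dice == rep.dice

    def test_empty_list(self):
        with pytest.raises(ValueError):
            aggregate_reports([])


class TestReportFrame:
    def test_schema(self):
        frame = report_frame({"m1": full_report(90.0), "m2": full_report(95.0)})
        assert list(frame.columns) == ["m1", "m2"]
        assert len(frame.index) == 13  # 12 metrics + weighted sum
        assert frame.loc["weighted_sum", "m1"] == 90.0
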