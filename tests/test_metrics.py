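"""Confusion matrix, precision/recall/F1, IoU, reports, and summaries."""

import numpy as np
import pytest

from sargamap import (
    CLASS_ORDER,
    ConfusionMatrix,
    Label,
    LabelMask,
    aggregate_rows,
    boxplot_summary,
    confusion,
    iou,
    iou_from_cm,
    precision_recall_f1,
    render_report,
    report,
    round_half_up,
    summarize_scores,
)
from sargamap.io_dataset import DimensionMismatchError


def mask_of(labels):
    return LabelMask(np.asarray(labels, dtype=np.uint8))


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self, random_mask_pair):
        t, _ = random_mask_pair(0)
        cm = confusion(t, t)
        assert np.all(cm.counts == np.diag(np.diag(cm.counts)))
        assert cm.total == t.labels.size

    def test_constant_sand_prediction(self):
        t = mask_of([[0] * 10 + [1] * 5 + [2] * 0])  # 10 sargassum, 5 sand
        p = mask_of([[1] * 15])
        cm = confusion(t, p)
        i_sarg = cm.classes.index(Label.SARGASSUM)
        i_sand = cm.classes.index(Label.SAND)
        assert cm.counts[i_sarg, i_sand] == 10
        assert cm.counts[i_sand, i_sand] == 5

    def test_grand_total_conserved(self, random_mask_pair):
        t, p = random_mask_pair(5)
        assert confusion(t, p).total == 32 * 32

    def test_dimension_mismatch(self):
        with pytest.raises(DimensionMismatchError):
            confusion(mask_of([[0, 1]]), mask_of([[0]]))


class TestPrecisionRecallF1:
    def test_equal_pr_gives_equal_f1(self):
        # P = R = 0.99 -> harmonic F1 = 0.99
        counts = np.array([[99, 1, 0], [1, 99, 0], [0, 0, 100]])
        cm = ConfusionMatrix(counts)
        got = precision_recall_f1(cm, Label.SARGASSUM)
        assert got["precision"] == pytest.approx(0.99)
        assert got["f1"] == pytest.approx(0.99)

    def test_worst_image_sand_row(self):
        """P 0.83, R 0.15 combine to F1 0.25 only under 2PR/(P+R); the
        printed-formula variant gives half of that."""
        p, r = 0.83, 0.15
        assert round_half_up(2 * p * r / (p + r)) == 0.25
        # same arithmetic through the module, via a matrix engineered to
        # those rates: TP=15, FN=85 (recall .15), FP=3 (precision 15/18=.833)
        cm = ConfusionMatrix(np.array([[15, 85, 0], [3, 197, 0], [0, 0, 100]]))
        got = precision_recall_f1(cm, Label.SARGASSUM)
        assert got["recall"] == pytest.approx(0.15)
        half = precision_recall_f1(cm, Label.SARGASSUM, harmonic=False)
        assert half["f1"] == pytest.approx(got["f1"] / 2)

    def test_empty_class_conventions(self):
        cm = ConfusionMatrix(np.array([[0, 0, 0], [0, 10, 0], [0, 0, 10]]))
        got = precision_recall_f1(cm, Label.SARGASSUM)
        assert got == {"precision": 0.0, "recall": 0.0, "f1": 0.0}


class TestReportAggregation:
    def test_identity_matrix_all_ones(self):
        rep = report(ConfusionMatrix(np.eye(3, dtype=int) * 10))
        assert rep.accuracy == 1.0
        assert rep.macro_avg["f1"] == 1.0
        assert rep.weighted_avg["f1"] == 1.0

    def test_mean_image_aggregates(self):
        """Per-class F1 (.96, .94, .83) with supports (19420, 32033, 14083)
        -> macro F1 0.91, weighted F1 0.92 after 2-decimal rounding."""
        rows = {
            Label.SARGASSUM: {"precision": 0.96, "recall": 0.96, "f1": 0.96, "support": 19420},
            Label.OTHER: {"precision": 0.90, "recall": 1.00, "f1": 0.94, "support": 32033},
            Label.SAND: {"precision": 0.97, "recall": 0.72, "f1": 0.83, "support": 14083},
        }
        agg = aggregate_rows(rows)
        assert round_half_up(agg["macro_avg"]["f1"]) == 0.91
        assert round_half_up(agg["weighted_avg"]["f1"]) == 0.92

    def test_worst_image_aggregates(self):
        rows = {
            Label.SARGASSUM: {"precision": 0.99, "recall": 0.97, "f1": 0.98, "support": 26499},
            Label.OTHER: {"precision": 0.63, "recall": 1.00, "f1": 0.77, "support": 23025},
            Label.SAND: {"precision": 0.83, "recall": 0.15, "f1": 0.25, "support": 16012},
        }
        agg = aggregate_rows(rows)
        assert round_half_up(agg["macro_avg"]["f1"]) == 0.67
        assert round_half_up(agg["weighted_avg"]["f1"]) == 0.73

    def test_equal_supports_collapse_weighted_to_macro(self):
        rows = {
            lab: {"precision": p, "recall": p, "f1": p, "support": 100}
            for lab, p in zip(CLASS_ORDER, (0.5, 0.7, 0.9))
        }
        agg = aggregate_rows(rows)
        assert agg["weighted_avg"] == pytest.approx(agg["macro_avg"])

    def test_report_agrees_with_naive_recount(self, random_mask_pair):
        """Cross-check against a per-pixel brute-force recount and the
        sklearn reference implementation."""
        t, p = random_mask_pair(11)
        rep = report(confusion(t, p))
        skm = pytest.importorskip("sklearn.metrics")
        ref_acc = skm.accuracy_score(t.labels.ravel(), p.labels.ravel())
        assert rep.accuracy == pytest.approx(ref_acc)
        pr, rc, f1, sup = skm.precision_recall_fscore_support(
            t.labels.ravel(), p.labels.ravel(), labels=[int(c) for c in CLASS_ORDER]
        )
        for i, cls in enumerate(CLASS_ORDER):
            assert rep.per_class[cls]["precision"] == pytest.approx(pr[i])
            assert rep.per_class[cls]["recall"] == pytest.approx(rc[i])
            assert rep.per_class[cls]["f1"] == pytest.approx(f1[i])
            assert rep.per_class[cls]["support"] == sup[i]

    def test_micro_f1_equals_accuracy(self, random_mask_pair):
        """Single-label multi-class: micro-averaged F1 equals accuracy."""
        t, p = random_mask_pair(21)
        cm = confusion(t, p)
        tp = sum(cm.one_vs_rest(c)[0] for c in CLASS_ORDER)
        fp = sum(cm.one_vs_rest(c)[1] for c in CLASS_ORDER)
        fn = sum(cm.one_vs_rest(c)[2] for c in CLASS_ORDER)
        micro_p = tp / (tp + fp)
        micro_r = tp / (tp + fn)
        micro_f1 = 2 * micro_p * micro_r / (micro_p + micro_r)
        assert micro_f1 == pytest.approx(report(cm).accuracy)

    def test_render_has_table_layout(self, random_mask_pair):
        t, p = random_mask_pair(2)
        text = render_report(report(confusion(t, p)))
        for token in ("Sargassum", "Other", "Sand", "accuracy", "macro avg", "weighted avg"):
            assert token in text


class TestIoU:
    def test_identical_sets(self, random_mask_pair):
        t, _ = random_mask_pair(0)
        assert iou(t, t, Label.SAND) == 1.0

    def test_disjoint_sets(self):
        t = mask_of([[0, 0, 2, 2]])
        p = mask_of([[2, 2, 0, 0]])
        assert iou(t, p, Label.SARGASSUM) == 0.0

    def test_partial_overlap(self):
        # |A| = |B| = 4 with overlap 2 -> 2/6
        t = mask_of([[0, 0, 0, 0, 2, 2, 2, 2]])
        p = mask_of([[2, 2, 0, 0, 0, 0, 2, 2]])
        assert iou(t, p, Label.SARGASSUM) == pytest.approx(2 / 6)

    def test_both_empty_is_one_single_empty_is_zero(self):
        t = mask_of([[2, 2]])
        p = mask_of([[2, 2]])
        assert iou(t, p, Label.SAND) == 1.0
        assert iou(t, mask_of([[1, 2]]), Label.SAND) == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_dice_jaccard_identity(self, seed, random_mask_pair):
        """F1 = 2J/(1+J) per class, from the same confusion matrix."""
        t, p = random_mask_pair(seed)
        cm = confusion(t, p)
        for cls in CLASS_ORDER:
            j = iou_from_cm(cm, cls)
            f1 = precision_recall_f1(cm, cls)["f1"]
            assert abs(f1 - 2 * j / (1 + j)) < 1e-12
            assert iou(t, p, cls) == pytest.approx(j)


class TestBoxplot:
    def test_simple_five_numbers(self):
        s = boxplot_summary([1, 2, 3, 4, 5])
        assert (s.q1, s.median, s.q3) == (2, 3, 4)
        assert s.outliers == []
        assert (s.lower_whisker, s.upper_whisker) == (1, 5)

    def test_extreme_point_is_outlier(self):
        s = boxplot_summary([1, 1, 1, 1, 100])
        assert s.outliers == [100.0]
        assert s.upper_whisker == 1.0

    def test_constant_data_degenerate(self):
        s = boxplot_summary([3.0] * 7)
        assert s.minimum == s.q1 == s.median == s.q3 == s.maximum == 3.0
        assert s.outliers == []

    def test_invariant_ordering(self):
        rng = np.random.default_rng(0)
        s = boxplot_summary(rng.normal(0, 1, 200))
        assert (
            s.minimum
            <= s.lower_whisker
            <= s.q1
            <= s.median
            <= s.q3
            <= s.upper_whisker
            <= s.maximum
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            boxplot_summary([])


class TestSummarizeScores:
    def test_two_images(self):
        got = summarize_scores([{"f1": 0.8}, {"f1": 1.0}])
        assert got["f1"]["mean"] == pytest.approx(0.9)
        assert got["f1"]["50%"] == pytest.approx(0.9)

    def test_identical_scores_zero_sd(self):
        got = summarize_scores([{"iou": 0.5}] * 5)
        assert got["iou"]["sd"] == 0.0

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            summarize_scores([{"f1": 1.0}])

    def test_reproducible_from_seeded_draws(self):
        rows = [
            {"f1": float(v)}
            for v in np.random.default_rng(99).uniform(0, 1, 200)
        ]
        assert summarize_scores(rows) == summarize_scores(list(rows))


class TestRounding:
    @pytest.mark.parametrize(
        "x,expect", [(0.005, 0.01), (0.985, 0.99), (0.25, 0.25), (0.7249, 0.72)]
    )
    def test_half_up(self, x, expect):
        assert round_half_up(x) == expect
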