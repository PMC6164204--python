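import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cytonuclei import (AnnotationError, ConfusionCounts, NucleusSpec,
                        aggregate_report, confusion_counts, per_nucleus_records,
                        pixel_metrics)
from cytonuclei.evaluation import ImageResult, PixelMetrics

counts_triples = st.tuples(st.integers(0, 10**6), st.integers(0, 10**6),
                           st.integers(0, 10**6))


def spec(abnormal=False):
    return NucleusSpec(center=(0, 0), axes=(1, 1), rotation=0.0,
                       mean_intensity=70.0, abnormal=abnormal)


class TestConfusionCounts:
    def test_perfect_prediction(self):
        gt = np.zeros((20, 20), dtype=bool)
        gt[5:15, 5:15] = True
        c = confusion_counts(gt, gt)
        assert (c.tp, c.fp, c.fn) == (100, 0, 0)

    def test_empty_prediction(self):
        gt = np.zeros((10, 10), dtype=bool)
        gt[:5, :] = True
        c = confusion_counts(np.zeros_like(gt), gt)
        assert (c.tp, c.fn) == (0, 50)

    def test_counts_partition_the_image(self):
        rng = np.random.default_rng(0)
        pred, gt = rng.random((17, 23)) > 0.5, rng.random((17, 23)) > 0.3
        c = confusion_counts(pred, gt)
        assert c.tp + c.fp + c.fn + c.tn == pred.size

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


class TestPixelMetrics:
    def test_worked_example(self):
        m = pixel_metrics(ConfusionCounts(tp=90, fp=10, fn=10, tn=0))
        assert m.precision == pytest.approx(0.9)
        assert m.recall == pytest.approx(0.9)
        assert m.f_measure == pytest.approx(0.9)
        assert m.jaccard == pytest.approx(90 / 110)
        assert m.dice == pytest.approx(0.9)

    def test_perfect_prediction_scores_one_everywhere(self):
        m = pixel_metrics(ConfusionCounts(tp=42, fp=0, fn=0, tn=10))
        assert (m.precision, m.recall, m.f_measure, m.jaccard, m.dice) == (1, 1, 1, 1, 1)

    def test_degenerate_conventions(self):
        m = pixel_metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=100))
        assert (m.precision, m.recall, m.f_measure) == (0.0, 0.0, 0.0)
        assert (m.jaccard, m.dice) == (1.0, 1.0)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(counts_triples)
    def test_algebraic_identities(self, triple):
        tp, fp, fn = triple
        m = pixel_metrics(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=0))
        assert abs(m.dice - 2 * m.jaccard / (1 + m.jaccard)) < 1e-12
        if m.precision + m.recall > 0:
            harmonic = 2 * m.precision * m.recall / (m.precision + m.recall)
            assert abs(m.f_measure - harmonic) < 1e-12

    def test_polarity_swap_swaps_counts_consistently(self):
        rng = np.random.default_rng(1)
        pred, gt = rng.random((15, 15)) > 0.5, rng.random((15, 15)) > 0.5
        c = confusion_counts(pred, gt)
        c_inv = confusion_counts(~pred, ~gt)
        assert (c_inv.tp, c_inv.tn, c_inv.fp, c_inv.fn) == (c.tn, c.tp, c.fn, c.fp)


class TestPerNucleusRecords:
    def make_labels(self):
        labels = np.zeros((30, 30), dtype=np.int32)
        labels[2:12, 2:12] = 1     # area 100
        labels[15:25, 15:25] = 2   # area 100
        return labels

    def test_full_coverage_detected(self):
        labels = self.make_labels()
        records = per_nucleus_records(labels > 0, labels, [spec(), spec(True)])
        assert all(r.recall == 1.0 and r.detected for r in records)
        assert [r.abnormal for r in records] == [False, True]

    def test_recall_exactly_at_tau_is_not_detected(self):
        labels = self.make_labels()
        pred = np.zeros_like(labels, dtype=bool)
        pred[2:12, 2:8] = True   # covers exactly 60 of 100 pixels of region 1
        records = per_nucleus_records(pred, labels, [spec(), spec()])
        assert records[0].recall == pytest.approx(0.6)
        assert not records[0].detected

    def test_detection_rule_application(self):
        labels = np.zeros((10, 30), dtype=np.int32)
        labels[:, :10], labels[:, 10:20], labels[:, 20:] = 1, 2, 3
        pred = np.zeros_like(labels, dtype=bool)
        pred[:7, :10] = True    # recall 0.7
        pred[:5, 10:20] = True  # recall 0.5
        pred[:9, 20:] = True    # recall 0.9
        records = per_nucleus_records(pred, labels, [spec()] * 3)
        assert [r.detected for r in records] == [True, False, True]

    def test_growing_prediction_never_undetects(self):
        labels = self.make_labels()
        rng = np.random.default_rng(2)
        pred = rng.random(labels.shape) > 0.4
        grown = pred | (rng.random(labels.shape) > 0.7)
        before = per_nucleus_records(pred, labels, [spec(), spec()])
        after = per_nucleus_records(grown, labels, [spec(), spec()])
        for b, a in zip(before, after):
            assert a.detected or not b.detected

    def test_missing_metadata_rejected(self):
        labels = self.make_labels()
        with pytest.raises(AnnotationError):
            per_nucleus_records(labels > 0, labels, [spec()])


class TestAggregateReport:
    def result(self, method, detected_flags, abnormal_flags=None, dice=0.9):
        abnormal_flags = abnormal_flags or [False] * len(detected_flags)
        nuclei = [
            type("R", (), {})  # placeholder replaced below
            for _ in detected_flags
        ]
        from cytonuclei.evaluation import NucleusRecord
        nuclei = [NucleusRecord(gt_label=i + 1, area=100, recall=1.0 if d else 0.0,
                                detected=d, abnormal=a)
                  for i, (d, a) in enumerate(zip(detected_flags, abnormal_flags))]
        metrics = PixelMetrics(precision=0.9, recall=0.9, f_measure=0.9,
                               jaccard=0.8, dice=dice)
        return ImageResult(image_id="img", method=method, metrics=metrics, nuclei=nuclei)

    def test_ndr_pooled_over_nuclei(self):
        report = aggregate_report([self.result("otsu", [True, False, True])])
        assert report.aggregates.loc["otsu", "ndr"] == pytest.approx(2 / 3)

    def test_all_detected_across_images(self):
        results = [self.result("otsu", [True, True]) for _ in range(5)]
        report = aggregate_report(results)
        assert report.aggregates.loc["otsu", "ndr"] == 1.0
        assert report.aggregates.loc["otsu", "n_nuclei"] == 10

    def test_no_abnormal_nuclei_yields_nan_sentinel(self):
        report = aggregate_report([self.result("otsu", [True, True])])
        assert np.isnan(report.aggregates.loc["otsu", "abnormal_ndr"])

    def test_abnormal_ndr_restricted_to_abnormal(self):
        report = aggregate_report(
            [self.result("otsu", [True, False, True], [False, True, True])])
        assert report.aggregates.loc["otsu", "abnormal_ndr"] == pytest.approx(0.5)

    def test_report_serialization_roundtrip(self, tmp_path):
        report = aggregate_report([self.result("otsu", [True]),
                                   self.result("kmeans", [False])])
        report.to_csv(tmp_path / "report.csv")
        report.to_json(tmp_path / "report.json")
        import pandas as pd, json
        df = pd.read_csv(tmp_path / "report.csv")
        assert len(df) == 2 and df["dsc_percent"].iloc[0] == pytest.approx(90.0)
        payload = json.loads((tmp_path / "report.json").read_text())
        assert {row["method"] for row in payload["aggregates"]} == {"otsu", "kmeans"}

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            aggregate_report([])
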