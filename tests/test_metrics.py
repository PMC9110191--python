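import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fpddi.metrics import (
    ConfusionCounts,
    confusion,
    evaluate_predictions,
    f1_from_precision_recall,
    roc_pr_curves,
    scalar_metrics,
)


def mann_whitney_auroc(labels, scores):
    """Exhaustive pairwise concordance oracle: P(random positive outscores a
    random negative), counting ties as one half."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_enumeration(self):
        c = confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)

    def test_perfect(self):
        c = confusion([1, 0, 1], [1, 0, 1])
        assert c.fp == c.fn == 0 and c.total == 3

    def test_inverted(self):
        c = confusion([1, 0, 1], [0, 1, 0])
        assert c.tp == c.tn == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])


class TestScalarMetrics:
    def test_perfect_prediction(self):
        m = scalar_metrics(ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
        assert (m.accuracy, m.precision, m.recall, m.f1, m.mcc) == (1, 1, 1, 1, 1)

    def test_published_f1_from_precision_recall(self):
        # printed precision/recall of the best entire-CV classifier
        assert round(f1_from_precision_recall(0.9253, 0.8685), 4) == 0.8960

    def test_mcc_hand_computed(self):
        # (2*3 - 1*2) / sqrt((3+2)(3+1)(2+2)(2+1)) = 4 / sqrt(240)
        m = scalar_metrics(ConfusionCounts(tp=2, fp=1, tn=3, fn=2))
        assert m.mcc == pytest.approx(4 / np.sqrt(240), abs=1e-12)

    def test_zero_division_policy(self):
        # no predicted positives: precision undefined -> 0; MCC factor 0 -> 0
        m = scalar_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert m.precision == 0.0 and m.f1 == 0.0 and m.mcc == 0.0
        assert m.accuracy == 0.5

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30),
           st.integers(0, 30))
    @settings(deadline=None, max_examples=200)
    def test_f1_two_form_identity(self, tp, fp, tn, fn):
        """2PR/(P+R) equals 2TP/(2TP+FN+FP) whenever both are defined."""
        if tp + fp == 0 or tp + fn == 0 or 2 * tp + fn + fp == 0:
            return
        m = scalar_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        assert m.f1 == pytest.approx(2 * tp / (2 * tp + fn + fp), abs=1e-12)

    @given(st.integers(1, 30), st.integers(1, 30), st.integers(1, 30),
           st.integers(1, 30))
    @settings(deadline=None, max_examples=100)
    def test_label_inversion_negates_mcc(self, tp, fp, tn, fn):
        m = scalar_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        inv = scalar_metrics(ConfusionCounts(tp=fn, fp=tn, tn=fp, fn=tp))
        assert inv.mcc == pytest.approx(-m.mcc, abs=1e-12)

    def test_ranges(self):
        m = scalar_metrics(ConfusionCounts(tp=3, fp=7, tn=2, fn=8))
        for v in (m.accuracy, m.precision, m.recall, m.f1):
            assert 0 <= v <= 1
        assert -1 <= m.mcc <= 1


class TestCurves:
    def test_perfect_ranking(self):
        labels = [1, 1, 1, 0, 0, 0]
        scores = [0.9, 0.8, 0.7, 0.3, 0.2, 0.1]
        roc, pr, auroc, aupr = roc_pr_curves(labels, scores)
        assert auroc == 1.0
        assert aupr == 1.0

    def test_scores_equal_labels(self):
        _, _, auroc, aupr = roc_pr_curves([1, 0, 1, 0], [1.0, 0.0, 1.0, 0.0])
        assert auroc == 1.0 and aupr == 1.0

    def test_roc_endpoints(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        scores = rng.random(30)
        roc, pr, _, _ = roc_pr_curves(labels, scores)
        assert tuple(roc[0, 1:]) == (0.0, 0.0)
        assert tuple(roc[-1, 1:]) == (1.0, 1.0)
        # TPR column equals the PR recall column (minus the PR anchor row)
        assert np.array_equal(roc[1:, 2], pr[1:, 1])

    def test_hand_ranked_example_matches_pairwise_count(self):
        labels = [1, 0, 1, 1, 0, 0]
        scores = [0.9, 0.8, 0.6, 0.6, 0.6, 0.1]
        _, _, auroc, _ = roc_pr_curves(labels, scores)
        assert auroc == pytest.approx(mann_whitney_auroc(labels, scores), abs=1e-12)

    def test_trapezoid_equals_concordance_oracle(self):
        """Trapezoidal area equals the Mann-Whitney statistic, ties as 1/2."""
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(4, 50))
            labels = rng.integers(0, 2, n)
            labels[:2] = [0, 1]
            # coarse score grid to force ties
            scores = rng.integers(0, 6, n) / 5.0
            _, _, auroc, _ = roc_pr_curves(labels, scores)
            assert auroc == pytest.approx(mann_whitney_auroc(labels, scores),
                                          abs=1e-12)

    def test_matches_reference_implementation(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        labels = rng.integers(0, 2, 200)
        labels[:2] = [0, 1]
        scores = rng.random(200).round(1)  # ties included
        _, _, auroc, _ = roc_pr_curves(labels, scores)
        assert auroc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_label_inversion_flips_auroc(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        scores = rng.random(50)
        _, _, auroc, _ = roc_pr_curves(labels, scores)
        _, _, auroc_inv, _ = roc_pr_curves(1 - labels, scores)
        assert auroc_inv == pytest.approx(1 - auroc, abs=1e-12)

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            roc_pr_curves([1, 1, 1], [0.1, 0.5, 0.9])

    def test_pr_anchor_is_first_attainable_precision(self):
        labels = [0, 1, 0, 1]
        scores = [0.9, 0.8, 0.3, 0.2]  # top-scored sample is negative
        _, pr, _, _ = roc_pr_curves(labels, scores)
        assert pr[0, 1] == 0.0  # recall anchor
        assert pr[0, 2] == pr[1, 2] == 0.0  # precision of the first threshold


class TestEvaluatePredictions:
    def test_report_consistency(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 100)
        labels[:2] = [0, 1]
        scores = np.clip(labels * 0.5 + rng.random(100) * 0.5, 0, 1)
        report = evaluate_predictions(labels, scores)
        assert report.counts.total == 100
        assert report.scalars.f1 == pytest.approx(
            f1_from_precision_recall(report.scalars.precision,
                                     report.scalars.recall), abs=1e-12,
        )
        assert 0 <= report.auroc <= 1 and 0 <= report.aupr <= 1
        assert report.metadata["threshold"] == 0.5

    def test_json_roundtrip(self, tmp_path):
        report = evaluate_predictions([1, 0, 1, 0], [0.9, 0.2, 0.7, 0.4])
        path = tmp_path / "report.json"
        report.to_json(path)
        import json

        loaded = json.loads(path.read_text())
        assert loaded["auroc"] == report.auroc
        assert loaded["counts"]["tp"] == report.counts.tp
        assert len(loaded["roc"]) == len(report.roc)
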