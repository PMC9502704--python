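"""Confusion metrics, curve construction and cross-validated aggregation."""

import numpy as np
import pandas as pd
import pytest

from wristgait.evaluation import (ConfusionCounts, apply_threshold,
                                  balanced_accuracy, confusion,
                                  crossval_report, metrics, roc_pr_curves)
from wristgait.io import AccelRecording
from wristgait.preprocessing import make_folds


class TestConfusion:
    def test_perfect_agreement(self):
        c = confusion([1, 0, 1, 0], [1, 0, 1, 0])
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 2, 0, 0)

    def test_complement(self):
        c = confusion([0, 1, 0, 1], [1, 0, 1, 0])
        assert c.tp == 0 and c.tn == 0 and c.fp == 2 and c.fn == 2

    def test_random_pair_matches_element_scan(self, rng):
        pred = rng.random(1000) < 0.3
        truth = rng.random(1000) < 0.2
        c = confusion(pred, truth)
        tp = sum(1 for p, t in zip(pred, truth) if p and t)
        tn = sum(1 for p, t in zip(pred, truth) if not p and not t)
        fp = sum(1 for p, t in zip(pred, truth) if p and not t)
        fn = sum(1 for p, t in zip(pred, truth) if not p and t)
        assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)
        assert c.total == 1000

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])


class TestMetrics:
    def test_worked_example(self):
        m = metrics(ConfusionCounts(tp=3, fp=1, fn=2, tn=4))
        assert m["accuracy"] == pytest.approx(70.0)
        assert m["sensitivity"] == pytest.approx(60.0)
        assert m["specificity"] == pytest.approx(80.0)
        assert m["precision"] == pytest.approx(75.0)

    def test_perfect_prediction(self):
        m = metrics(ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
        assert all(v == pytest.approx(100.0) for v in m.values())

    def test_undefined_precision_flagged(self):
        m = metrics(ConfusionCounts(tp=0, fp=0, fn=3, tn=7))
        assert np.isnan(m["precision"])

    def test_balanced_accuracy_is_mean_of_se_sp(self):
        c = ConfusionCounts(tp=3, fp=1, fn=2, tn=4)
        assert balanced_accuracy(c) == pytest.approx((60 + 80) / 2)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(0, 0, 0, 0))


def mann_whitney_auc(scores, truth):
    """All-pairs comparison probability with ties half-weighted."""
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestCurves:
    def test_perfect_separation(self):
        truth = np.array([0, 0, 1, 1])
        roc, pr = roc_pr_curves([0.1, 0.2, 0.8, 0.9], truth)
        assert roc.auc == pytest.approx(1.0)
        assert pr.auc == pytest.approx(1.0)

    def test_roc_endpoints(self, rng):
        roc, _ = roc_pr_curves(rng.random(50), rng.integers(0, 2, 50))
        assert (roc.x[0], roc.y[0]) == (0.0, 0.0)
        assert (roc.x[-1], roc.y[-1]) == (1.0, 1.0)

    def test_independent_scores_auc_near_half(self, rng):
        truth = rng.integers(0, 2, 20000)
        roc, _ = roc_pr_curves(rng.random(20000), truth)
        assert roc.auc == pytest.approx(0.5, abs=0.03)

    def test_roc_auc_equals_mann_whitney_with_ties(self, rng):
        scores = rng.integers(0, 20, 200).astype(float)  # heavy ties
        truth = rng.integers(0, 2, 200)
        roc, _ = roc_pr_curves(scores, truth)
        assert abs(roc.auc - mann_whitney_auc(scores, truth)) < 1e-10

    def test_pr_auc_of_random_scores_near_prevalence(self, rng):
        truth = (rng.random(20000) < 0.15).astype(int)
        _, pr = roc_pr_curves(rng.random(20000), truth)
        assert pr.auc == pytest.approx(0.15, abs=0.05)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            roc_pr_curves(rng.random(10), np.ones(10, dtype=int))


class TestApplyThreshold:
    def test_all_positive(self):
        assert apply_threshold([0.95] * 4, 0.9).sum() == 4

    def test_nesting(self, rng):
        p = rng.random(500)
        hi = apply_threshold(p, 0.9)
        lo = apply_threshold(p, 0.5)
        assert not (hi & ~lo).any()

    def test_count_matches_scan(self, rng):
        p = rng.random(300)
        assert apply_threshold(p, 0.9).sum() == sum(1 for v in p if v > 0.9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            apply_threshold([1.2])


class TestCrossvalReport:
    def _recs(self, rng, n=6):
        recs = []
        for i in range(n):
            mask = (rng.random(500) < 0.3).astype(int)
            recs.append(AccelRecording(acc=rng.normal(size=(500, 3)), fs=25.0,
                                       subject_id=f"s{i}", mask=mask))
        return recs

    @staticmethod
    def _oracle_run(train, test):
        """Deterministic pseudo-detector: noisy copy of the truth."""
        probs, truth = [], []
        for rec in test:
            local = np.random.default_rng(hash(rec.subject_id) % 2**31)
            p = np.clip(rec.mask * 0.8 + local.random(rec.n_samples) * 0.2, 0, 1)
            probs.append(p)
            truth.append(rec.mask)
        return np.concatenate(probs), np.concatenate(truth)

    def test_reproducible_and_mean_bounded(self, rng):
        recs = self._recs(rng)
        folds = make_folds([r.subject_id for r in recs], k=3, seed=0)
        rep1 = crossval_report(recs, self._oracle_run, folds, threshold=0.5)
        rep2 = crossval_report(recs, self._oracle_run, folds, threshold=0.5)
        pd.testing.assert_frame_equal(rep1.per_fold, rep2.per_fold)
        for col in rep1.per_fold:
            assert rep1.per_fold[col].min() - 1e-9 <= rep1.mean[col] \
                <= rep1.per_fold[col].max() + 1e-9

    def test_std_requires_two_folds(self, rng):
        rep = crossval_report(self._recs(rng, 3),
                              self._oracle_run,
                              make_folds(["s0", "s1", "s2"], k=3, seed=0),
                              threshold=0.5)
        assert len(rep.per_fold) == 3
        assert (rep.std >= 0).all()

    def test_binary_detector_carries_no_auc(self, rng):
        recs = self._recs(rng)
        folds = make_folds([r.subject_id for r in recs], k=3, seed=0)

        def binary_run(train, test):
            p, t = self._oracle_run(train, test)
            return (p > 0.5).astype(float), t

        rep = crossval_report(recs, binary_run, folds, threshold=0.5,
                              continuous=False)
        assert "roc_auc" not in rep.per_fold.columns
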