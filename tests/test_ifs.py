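"""IFS machinery: SMOTE, stratified folds, metrics, CV and the sweep."""

import numpy as np
import pytest

from genesieve.ifs import (
    ConfusionCounts,
    IFSConfig,
    cv_evaluate,
    evaluate_metrics,
    ifs_run,
    prefix_sizes,
    smote_oversample,
    stratified_folds,
)


class TestSmote:
    def test_two_points_interpolate_on_segment(self):
        X = np.array([[0.0, 0.0], [1.0, 2.0]])
        synth = smote_oversample(X, 50, k=1, seed=1)
        assert synth.shape == (50, 2)
        assert np.all(synth[:, 0] >= 0) and np.all(synth[:, 0] <= 1)
        assert np.all(synth[:, 1] >= 0) and np.all(synth[:, 1] <= 2)
        # points lie on the segment: y = 2x
        assert np.allclose(synth[:, 1], 2 * synth[:, 0])

    def test_zero_requested_rows(self):
        X = np.array([[0.0], [1.0]])
        assert smote_oversample(X, 0).shape == (0, 1)

    def test_coordinatewise_between_parents(self, rng):
        X = rng.random((40, 5))
        synth, base, neigh = smote_oversample(
            X, 2000, k=5, seed=7, return_parents=True
        )
        lo = np.minimum(X[base], X[neigh])
        hi = np.maximum(X[base], X[neigh])
        assert np.all(synth >= lo - 1e-12) and np.all(synth <= hi + 1e-12)

    def test_single_minority_sample_rejected(self):
        with pytest.raises(ValueError, match="two minority"):
            smote_oversample(np.array([[1.0, 2.0]]), 5)


class TestStratifiedFolds:
    def test_exact_divisibility(self):
        y = np.array([1] * 20 + [0] * 80)
        folds = stratified_folds(y, 10, seed=0)
        for f in range(10):
            assert (y[folds == f] == 1).sum() == 2
            assert (y[folds == f] == 0).sum() == 8

    def test_partition(self):
        y = np.array([1] * 33 + [0] * 67)
        folds = stratified_folds(y, 10, seed=1)
        assert folds.shape == y.shape
        assert set(np.unique(folds)) == set(range(10))

    def test_pigeonhole_counts(self):
        y = np.array([1] * 13 + [0] * 40)
        folds = stratified_folds(y, 10, seed=2)
        pos_counts = [(y[folds == f] == 1).sum() for f in range(10)]
        assert set(pos_counts) <= {1, 2}
        assert sum(pos_counts) == 13

    def test_small_class_rejected(self):
        y = np.array([1] * 5 + [0] * 95)
        with pytest.raises(ValueError, match="fewer than"):
            stratified_folds(y, 10)


class TestEvaluateMetrics:
    def test_symmetric_counts(self):
        m = evaluate_metrics(ConfusionCounts(1, 1, 1, 1))
        assert (m.acc, m.sn, m.sp, m.precision, m.f1, m.mcc) == (
            0.5, 0.5, 0.5, 0.5, 0.5, 0.0,
        )

    def test_perfect_classifier(self):
        m = evaluate_metrics(ConfusionCounts(tp=10, tn=40, fp=0, fn=0))
        assert m.acc == m.sn == m.sp == m.precision == m.f1 == 1.0
        assert m.mcc == 1.0

    def test_f1_from_reported_precision_recall(self):
        """F1 recomposed from precision 0.378 / recall 0.683 is 0.4866,
        i.e. 0.486 within input-rounding."""
        precision, recall = 0.378, 0.683
        f1 = 2 * precision * recall / (precision + recall)
        assert f1 == pytest.approx(0.486, abs=1e-3)

    def test_zero_denominators_define_zero(self):
        m = evaluate_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=5))
        assert m.precision == 0.0 and m.f1 == 0.0 and m.mcc == 0.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            evaluate_metrics(ConfusionCounts(0, 0, 0, 0))


def _separable(n=120, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([1] * 30 + [0] * 90)
    X = y[:, None] + 0.01 * rng.standard_normal((n, 1))
    return X, y


class TestCvEvaluate:
    def test_perfectly_separable_scores_one(self):
        X, y = _separable()
        rec, pooled = cv_evaluate(X, y, IFSConfig(seed=3))
        assert rec.f1 == 1.0 and rec.mcc == 1.0 and rec.acc == 1.0

    def test_pooled_counts_cover_every_sample_once(self):
        rng = np.random.default_rng(1)
        y = np.array([1] * 25 + [0] * 75)
        X = rng.standard_normal((100, 4))
        _, pooled = cv_evaluate(X, y, IFSConfig(seed=1))
        assert pooled.total == 100
        assert pooled.tp + pooled.fn == 25
        assert pooled.tn + pooled.fp == 75

    def test_pure_noise_mcc_near_zero(self):
        mccs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            y = np.array([1] * 100 + [0] * 100)
            X = rng.standard_normal((200, 5))
            rec, _ = cv_evaluate(X, y, IFSConfig(seed=seed))
            mccs.append(rec.mcc)
        assert np.mean(np.abs(mccs)) < 0.15

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(9)
        y = np.array([1] * 30 + [0] * 70)
        X = rng.standard_normal((100, 3))
        r1, _ = cv_evaluate(X, y, IFSConfig(seed=5))
        r2, _ = cv_evaluate(X, y, IFSConfig(seed=5))
        assert r1 == r2


class TestIfsRun:
    def test_prefix_sizes_include_final_partial(self):
        assert prefix_sizes(7, 5) == [5, 7]
        assert prefix_sizes(20, 5) == [5, 10, 15, 20]
        assert prefix_sizes(3, 5) == [3]

    def test_tie_goes_to_smaller_prefix(self):
        """A perfectly separating first column gives equal F1 = 1 at every
        prefix; the tie rule must pick the smallest."""
        X, y = _separable()
        rng = np.random.default_rng(2)
        X7 = np.hstack([X, rng.standard_normal((len(y), 6))])
        curve = ifs_run(X7, y, IFSConfig(step=5, seed=2))
        assert [n for n, _ in curve.points] == [5, 7]
        assert all(rec.f1 == 1.0 for _, rec in curve.points)
        assert curve.best[0] == 5

    def test_curve_deterministic(self):
        rng = np.random.default_rng(4)
        y = np.array([1] * 30 + [0] * 70)
        X = rng.standard_normal((100, 8))
        c1 = ifs_run(X, y, IFSConfig(seed=11))
        c2 = ifs_run(X, y, IFSConfig(seed=11))
        assert c1 == c2
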