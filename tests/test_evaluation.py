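"""Metrics: oracle comparisons, closed-form integration checks, guards."""

import warnings

import numpy as np
import pytest

from ccdnet.metrics import (
    ConfusionCounts,
    accuracy,
    confusion,
    f_score,
    integrate_depth,
    roc_auc,
)
from ccdnet.segment import PulseSegment
from ccdnet.simulate import SimulatorConfig, make_dataset


def u_statistic_auc(scores, labels):
    """Pairwise Mann-Whitney oracle: P(pos > neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_prediction(self):
        c = confusion([1, 0], [1, 0])
        assert (c.TP, c.TN, c.FP, c.FN) == (1, 1, 0, 0)

    def test_false_positive_definition(self):
        assert confusion([1], [0]).FP == 1

    def test_against_brute_force_tally(self, rng):
        pred = rng.integers(0, 2, size=1000)
        act = rng.integers(0, 2, size=1000)
        c = confusion(pred, act)
        tally = {"TP": 0, "TN": 0, "FP": 0, "FN": 0}
        for p, a in zip(pred, act):
            key = ("T" if p == a else "F") + ("P" if p == 1 else "N")
            tally[key] += 1
        assert (c.TP, c.TN, c.FP, c.FN) == (
            tally["TP"], tally["TN"], tally["FP"], tally["FN"],
        )

    def test_label_swap_maps_counts_and_accuracy(self, rng):
        pred = rng.integers(0, 2, size=200)
        act = rng.integers(0, 2, size=200)
        c = confusion(pred, act)
        swapped = confusion(1 - pred, act)
        assert (swapped.TP, swapped.TN, swapped.FP, swapped.FN) == (c.FN, c.FP, c.TN, c.TP)
        assert accuracy(swapped) == pytest.approx(1 - accuracy(c))

    def test_validation(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])
        with pytest.raises(ValueError):
            confusion([2], [1])
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)


class TestAccuracyFScore:
    def test_accuracy_arithmetic(self):
        assert accuracy(ConfusionCounts(1, 1, 0, 0)) == 1.0
        assert accuracy(ConfusionCounts(50, 45, 5, 20)) == pytest.approx(95 / 120)
        assert accuracy(ConfusionCounts(0, 0, 7, 0)) == 0.0

    def test_accuracy_needs_counts(self):
        with pytest.raises(ValueError):
            accuracy(ConfusionCounts(0, 0, 0, 0))

    def test_f_score_worked_values(self):
        assert f_score(ConfusionCounts(8, 0, 2, 4)) == pytest.approx(8 / 11)
        assert f_score(ConfusionCounts(0, 5, 3, 2)) == 0.0

    def test_f_equals_p_when_p_equals_r(self):
        # P = R = 0.8
        assert f_score(ConfusionCounts(8, 0, 2, 2)) == pytest.approx(0.8)

    def test_bounds_and_perfection(self, rng):
        for _ in range(50):
            c = ConfusionCounts(*rng.integers(0, 30, size=4))
            if c.total == 0:
                continue
            assert 0 <= accuracy(c) <= 1
            assert 0 <= f_score(c) <= 1
        assert f_score(ConfusionCounts(10, 5, 0, 0)) == 1.0


class TestROC:
    def test_perfect_separation(self):
        roc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert roc.auc == 1.0
        assert roc.fpr[0] == 0 and roc.tpr[0] == 0
        assert roc.fpr[-1] == 1 and roc.tpr[-1] == 1

    def test_random_scores_near_half(self, rng):
        y = np.r_[np.ones(1000, dtype=int), np.zeros(1000, dtype=int)]
        s = rng.random(2000)
        assert roc_auc(s, y).auc == pytest.approx(0.5, abs=0.05)

    def test_matches_u_statistic_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 30))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            s = np.round(rng.random(n), 2)  # coarse grid forces ties
            assert roc_auc(s, y).auc == pytest.approx(u_statistic_auc(s, y), abs=1e-12)

    def test_matches_reference_implementation(self, rng):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        y = rng.integers(0, 2, size=500)
        y[:2] = [0, 1]
        s = rng.random(500)
        assert roc_auc(s, y).auc == pytest.approx(
            sklearn_metrics.roc_auc_score(y, s), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, size=300)
        y[:2] = [0, 1]
        s = rng.normal(size=300)
        a = roc_auc(s, y).auc
        b = roc_auc(np.exp(2 * s) + 3, y).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_monotone_curve(self, rng):
        y = rng.integers(0, 2, size=100)
        y[:2] = [0, 1]
        roc = roc_auc(rng.random(100), y)
        assert np.all(np.diff(roc.tpr) >= 0)
        assert np.all(np.diff(roc.fpr) >= 0)


class TestIntegrateDepth:
    def test_constant_acceleration_closed_form(self):
        # 1 m/s^2 for 0.3 s from rest: x = a t^2 / 2 = 0.045 m
        dt = 0.005
        seg = PulseSegment(np.ones(61), 0, 61, 30)
        depth, label = integrate_depth(seg, dt)
        assert depth == pytest.approx(45.0, rel=0.01)
        assert label == 0

    def test_zero_acceleration(self):
        seg = PulseSegment(np.zeros(40), 0, 40, 10)
        depth, label = integrate_depth(seg, 0.005)
        assert depth == 0.0 and label == 0

    def test_raised_cosine_closed_form(self):
        # a(t) = A/2 (1 - cos(2 pi t / T)) from rest: x(T) = A T^2 / 4
        A, T, dt = 2.0, 0.4, 0.005
        n = int(T / dt) + 1
        t = np.arange(n) * dt
        seg = PulseSegment(A * 0.5 * (1 - np.cos(2 * np.pi * t / T)), 0, n, n // 2)
        depth, _ = integrate_depth(seg, dt)
        assert depth == pytest.approx(1000 * A * T**2 / 4, rel=0.01)

    def test_baseline_resolution_order(self):
        seg = PulseSegment(np.ones(61), 0, 61, 30, baseline=1.0)
        depth, label = integrate_depth(seg, 0.005)
        assert depth == 0.0  # recorded baseline removed
        depth2, _ = integrate_depth(seg, 0.005, baseline=0.0)
        assert depth2 == pytest.approx(45.0, rel=0.01)

    def test_degenerate_inputs_rejected(self):
        seg = PulseSegment(np.ones(2), 0, 2, 0)
        with pytest.raises(ValueError):
            integrate_depth(seg, 0.005)
        seg = PulseSegment(np.ones(10), 0, 10, 0)
        with pytest.raises(ValueError):
            integrate_depth(seg, 0.0)


class TestIntegrationVsClassifierGuard:
    def test_drift_degrades_integration_below_cnn(self, scfg72):
        """Soft guard: under drift the CNN should beat double integration."""
        from ccdnet.api import CompressionQualityCNN
        from ccdnet.pipeline import stratified_split

        cfg = SimulatorConfig.separable(seed=31, drift_sd=0.004)
        data = make_dataset(240, 0.5, cfg, segmentation_config=scfg72)
        train_set, test_set, _ = stratified_split(data, 160, 60, seed=3)
        res = CompressionQualityCNN(train_set, arch="cpcnn4").fit(iterations=150, seed=0)
        cnn_acc = res.evaluate(test_set)["accuracy"]
        pred = np.array(
            [integrate_depth(s, data.sampling_interval)[1] for s in test_set.segments]
        )
        integ_acc = accuracy(confusion(pred, test_set.y))
        if integ_acc >= cnn_acc:
            warnings.warn(
                f"integration baseline ACC {integ_acc:.3f} >= CNN ACC {cnn_acc:.3f} "
                "under drift (soft guard)"
            )
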