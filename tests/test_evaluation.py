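"""Metric oracles: accuracy, sens/spec, ROC/AUC, bootstrap, Fleiss, regions."""

import numpy as np
import pytest

from lvscar.evaluation import (
    accuracy,
    bootstrap_ci,
    evaluate,
    fleiss_kappa,
    region_rollup,
    roc_auc,
    sensitivity_specificity,
)


def mann_whitney_auc(scores, labels):
    """Brute-force pairwise AUC with half-credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAccuracy:
    def test_four_of_five(self):
        assert accuracy([1, 0, 1, 1, 0], [1, 0, 1, 0, 0]) == 0.8

    def test_all_correct(self):
        assert accuracy([1, 1, 0], [1, 1, 0]) == 1.0

    def test_random_matches_counting_oracle(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 2, 100)
        labels = rng.integers(0, 2, 100)
        n_correct = sum(1 for c, l in zip(calls, labels) if c == l)
        assert accuracy(calls, labels) == n_correct / 100

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            accuracy([], [])


class TestSensitivitySpecificity:
    def test_perfect(self):
        assert sensitivity_specificity([1, 0, 1], [1, 0, 1]) == (1.0, 1.0)

    def test_all_positive_calls(self):
        assert sensitivity_specificity([1, 1, 1, 1], [1, 0, 1, 0]) == (1.0, 0.0)

    def test_hand_computed_confusion(self):
        # TP=3 FN=1 TN=4 FP=2
        labels = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        calls = [1, 1, 1, 0, 1, 1, 0, 0, 0, 0]
        sens, spec = sensitivity_specificity(calls, labels)
        assert sens == pytest.approx(0.75)
        assert spec == pytest.approx(2.0 / 3.0)

    def test_single_class_raises_naming_absent_class(self):
        with pytest.raises(ValueError, match="negative"):
            sensitivity_specificity([1, 1], [1, 1])
        with pytest.raises(ValueError, match="positive"):
            sensitivity_specificity([0, 0], [0, 0])


class TestROCAUC:
    def test_perfect_separation(self):
        auc, _ = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_matches_mann_whitney_with_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            scores = np.round(rng.random(30), 1)  # heavy ties
            labels = rng.integers(0, 2, 30)
            if len(np.unique(labels)) < 2:
                continue
            auc, _ = roc_auc(scores, labels)
            assert auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(1)
        scores = rng.random(2000)
        labels = rng.integers(0, 2, 2000)
        auc, _ = roc_auc(scores, labels)
        assert abs(auc - 0.5) < 0.05

    def test_roc_points_monotone(self):
        rng = np.random.default_rng(2)
        _, pts = roc_auc(rng.random(50), rng.integers(0, 2, 50))
        fpr = [p[0] for p in pts]
        tpr = [p[1] for p in pts]
        assert all(b >= a for a, b in zip(fpr, fpr[1:]))
        assert all(b >= a for a, b in zip(tpr, tpr[1:]))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        a1, _ = roc_auc(scores, labels)
        a2, _ = roc_auc(np.exp(3 * scores) - 0.5, labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestBootstrap:
    def test_constant_statistic_zero_width(self):
        rng = np.random.default_rng(0)
        lo, hi = bootstrap_ci(
            rng.random(40), rng.integers(0, 2, 40), lambda p, y: 0.7, n_boot=50
        )
        assert lo == hi == 0.7

    def test_interval_contains_point_estimate(self):
        rng = np.random.default_rng(4)
        probs = np.clip(rng.normal(0.5, 0.2, 200) + 0.2 * rng.integers(0, 2, 200), 0, 1)
        labels = rng.integers(0, 2, 200)
        stat = lambda p, y: float(((p >= 0.5).astype(int) == y).mean())
        lo, hi = bootstrap_ci(probs, labels, stat, n_boot=500, seed=1)
        assert lo <= stat(probs, labels) <= hi

    def test_sd_band_available(self):
        rng = np.random.default_rng(6)
        probs, labels = rng.random(50), rng.integers(0, 2, 50)
        stat = lambda p, y: float(p.mean())
        lo, hi = bootstrap_ci(probs, labels, stat, n_boot=200, seed=0, band="sd")
        assert lo < hi

    def test_percentile_coverage_near_nominal(self):
        # 500 replications of n=80 binomial accuracy data; the 95% percentile
        # interval should cover the true value about 95% of the time
        rng = np.random.default_rng(8)
        true_p = 0.8
        covered = 0
        reps = 500
        for i in range(reps):
            labels = rng.integers(0, 2, 80)
            correct = rng.random(80) < true_p
            calls = np.where(correct, labels, 1 - labels)
            stat = lambda c, y: float((c == y).mean())
            lo, hi = bootstrap_ci(
                calls.astype(float), labels, stat, n_boot=300, seed=i
            )
            covered += lo <= true_p <= hi
        assert abs(covered / reps - 0.95) <= 0.03


class TestFleissKappa:
    def test_perfect_agreement_is_one(self):
        ratings = np.tile(np.array([[1], [0], [1], [0], [1]]), (1, 4))
        assert fleiss_kappa(ratings) == pytest.approx(1.0)

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(9)
        ratings = rng.integers(0, 2, size=(10_000, 3))
        assert abs(fleiss_kappa(ratings)) < 0.02

    def test_hand_computed_six_item_fixture(self):
        # per-item agreement P = [1, 1/3, 1, 1/3, 1/3, 1]; P_bar = 2/3;
        # marginals p1 = 10/18, p0 = 8/18; P_e = 41/81; kappa = 13/40
        ratings = np.array(
            [[1, 1, 1], [1, 1, 0], [0, 0, 0], [1, 0, 0], [0, 0, 1], [1, 1, 1]]
        )
        assert fleiss_kappa(ratings) == pytest.approx(13.0 / 40.0, abs=1e-12)

    def test_unanimous_single_category_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            fleiss_kappa(np.ones((5, 3), dtype=int))

    def test_bad_shapes_rejected(self):
        with pytest.raises(ValueError):
            fleiss_kappa(np.array([[1, 0]]))


class TestRegionRollup:
    def test_apical_positives_only(self):
        calls = [1, 1, 0, 0, 0]
        pos = [0.10, 0.20, 0.40, 0.60, 0.80]
        out = region_rollup(calls, pos)
        assert out == {"apex": True, "mid": False, "base": False}

    def test_no_positives(self):
        out = region_rollup([0, 0, 0], [0.1, 0.5, 0.9])
        assert out == {"apex": False, "mid": False, "base": False}

    def test_straddling_the_apex_mid_boundary(self):
        calls = [1, 1, 0]
        pos = [0.32, 0.35, 0.9]
        out = region_rollup(calls, pos)
        assert out["apex"] is True and out["mid"] is True and out["base"] is False

    def test_empty_region_indeterminate(self):
        out = region_rollup([1, 0], [0.1, 0.2])
        assert out["apex"] is True and out["mid"] is None and out["base"] is None


class TestReportInvariants:
    def test_accuracy_identity_with_sens_spec(self):
        rng = np.random.default_rng(10)
        for _ in range(5):
            probs = rng.random(120)
            labels = rng.integers(0, 2, 120)
            calls = (probs >= 0.5).astype(int)
            sens, spec = sensitivity_specificity(calls, labels)
            n_pos = labels.sum()
            n_neg = len(labels) - n_pos
            expect = (sens * n_pos + spec * n_neg) / len(labels)
            assert accuracy(calls, labels) == pytest.approx(expect, abs=1e-12)

    def test_label_reversal_swaps_sens_and_spec(self):
        rng = np.random.default_rng(12)
        calls = rng.integers(0, 2, 60)
        labels = rng.integers(0, 2, 60)
        s1, p1 = sensitivity_specificity(calls, labels)
        s2, p2 = sensitivity_specificity(1 - calls, 1 - labels)
        assert (s1, p1) == (s2, p2)[::-1] or (s1 == p2 and p1 == s2)
        assert accuracy(calls, labels) == accuracy(1 - calls, 1 - labels)

    def test_evaluate_report_fields_consistent(self):
        rng = np.random.default_rng(13)
        labels = rng.integers(0, 2, 100)
        probs = np.clip(labels * 0.4 + rng.random(100) * 0.6, 0, 1)
        rep = evaluate(probs, labels, n_boot=200)
        assert 0 <= rep.accuracy <= 1 and 0 <= rep.auc <= 1
        assert rep.ci_low <= rep.auc <= rep.ci_high
        assert rep.n_samples == 100 and rep.n_positive == labels.sum()
        assert "accuracy" in rep.summary()
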