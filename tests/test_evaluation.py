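import numpy as np
import pytest

from newsfio2 import (UndefinedMetricError, admission_level_summary, auroc,
                      auroc_by_window, bootstrap_auroc_ci, efficiency_curve,
                      evaluate, operating_point, per_thousand_gains, pr_curve,
                      roc_curve_points)

from conftest import brute_force_auroc


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([1, 2, 10, 11], [False, False, True, True]) == 1.0

    def test_frozen_tie_case(self):
        # pair enumeration: pos {2, 3} vs neg {1, 2} gives three wins and one
        # tie counted one half -> (3 + 0.5) / 4 = 0.875
        scores, labels = [1, 2, 2, 3], [False, True, False, True]
        assert auroc(scores, labels) == 0.875
        assert brute_force_auroc(scores, labels) == 0.875

    def test_single_class_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auroc([1, 2, 3], [True, True, True])

    def test_agrees_with_all_pairs_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(10, 400))
            scores = rng.integers(0, 15, n).astype(float)
            labels = rng.random(n) < 0.3
            if labels.all() or not labels.any():
                continue
            assert auroc(scores, labels) == pytest.approx(
                brute_force_auroc(scores, labels), abs=1e-12)

    def test_agrees_with_sklearn(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(1)
        scores = rng.normal(size=2000)
        labels = rng.random(2000) < 0.2
        assert auroc(scores, labels) == pytest.approx(
            sk.roc_auc_score(labels, scores), abs=1e-12)

    def test_null_scores_give_half(self):
        rng = np.random.default_rng(2)
        n = 100_000
        scores = rng.normal(size=n)
        labels = rng.random(n) < 0.05
        assert auroc(scores, labels) == pytest.approx(0.5, abs=0.01)

    def test_invariant_under_strictly_increasing_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=500)
        labels = rng.random(500) < 0.4
        assert auroc(scores, labels) == pytest.approx(
            auroc(np.exp(scores), labels), abs=1e-12)


class TestBootstrapCI:
    def test_degenerate_separation_gives_unit_interval(self):
        lo, hi = bootstrap_auroc_ci([0, 0, 5, 5], [False, False, True, True],
                                    reps=50, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=500) + rng.random(500)
        labels = rng.random(500) < 0.2
        a = bootstrap_auroc_ci(scores, labels, reps=100, seed=42)
        b = bootstrap_auroc_ci(scores, labels, reps=100, seed=42)
        assert a == b

    def test_prevalence_preserved_interval_brackets_point(self):
        rng = np.random.default_rng(5)
        labels = rng.random(3000) < 0.03
        scores = rng.normal(size=3000) + 1.2 * labels
        point = auroc(scores, labels)
        lo, hi = bootstrap_auroc_ci(scores, labels, reps=300, seed=0)
        assert lo <= point <= hi

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_auroc_ci([0, 1], [False, True], reps=1)


class TestOperatingPoint:
    def test_hand_contingency_table(self):
        # TP=8, FN=2, FP=40, TN=50 at threshold 5
        scores = [5] * 8 + [0] * 2 + [5] * 40 + [0] * 50
        labels = [True] * 10 + [False] * 90
        op = operating_point(scores, labels, 5)
        assert op.sensitivity == pytest.approx(80.0)
        assert op.specificity == pytest.approx(55.6, abs=0.05)
        assert op.ppv == pytest.approx(16.7, abs=0.05)
        assert op.efficiency == pytest.approx(48.0)

    def test_threshold_zero_alerts_everything(self):
        op = operating_point([1, 3, 2], [True, False, True], 0)
        assert op.sensitivity == 100.0 and op.specificity == 0.0

    def test_threshold_above_max_score(self):
        op = operating_point([1, 3, 2], [True, False, True], 99)
        assert op.sensitivity == 0.0 and op.efficiency == 0.0
        assert op.ppv is None

    def test_self_consistent_confusion_counts(self):
        rng = np.random.default_rng(6)
        scores = rng.integers(0, 12, 500)
        labels = rng.random(500) < 0.2
        op = operating_point(scores, labels, 5)
        assert op.tp + op.fn == labels.sum()
        assert op.sensitivity == pytest.approx(100 * op.tp / (op.tp + op.fn))
        assert op.efficiency == pytest.approx(100 * (op.tp + op.fp) / 500)


class TestAurocByWindow:
    def test_full_window_matches_standard_auroc(self):
        rng = np.random.default_rng(7)
        labels = rng.random(2000) < 0.1
        scores = rng.normal(size=2000) + labels
        tte = [float(rng.uniform(0, 24)) if l else None for l in labels]
        pts = auroc_by_window(scores, labels, tte, [24])
        assert pts[0][1] == pytest.approx(auroc(scores, labels))

    def test_weakly_increasing_when_scores_drift_toward_event(self):
        rng = np.random.default_rng(8)
        labels = rng.random(20_000) < 0.1
        tte = np.where(labels, rng.uniform(0, 24, 20_000), np.nan)
        # score rises as the event gets closer
        scores = rng.normal(size=20_000) + np.where(labels, 2.5 * (1 - tte / 24), 0.0)
        pts = auroc_by_window(scores, labels,
                              [None if not l else float(t)
                               for l, t in zip(labels, tte)],
                              [24, 16, 8, 4, 1])
        vals = [a for _, a in pts]
        assert all(b >= a - 0.01 for a, b in zip(vals, vals[1:]))

    def test_zero_window_reports_missing(self):
        pts = auroc_by_window([1, 2, 3], [False, True, False], [None, 5.0, None],
                              [24, 0])
        assert pts[-1] == (0.0, None)


class TestCurves:
    FIXTURE_SCORES = [0, 1, 1, 2, 3, 3]
    FIXTURE_LABELS = [False, False, True, False, True, True]

    def test_efficiency_curve_hand_fixture(self):
        pts = efficiency_curve(self.FIXTURE_SCORES, self.FIXTURE_LABELS)
        # thresholds descending 3,2,1,0
        assert pts[0] == (3.0, pytest.approx(2 / 6), pytest.approx(2 / 3))
        assert pts[1] == (2.0, pytest.approx(3 / 6), pytest.approx(2 / 3))
        assert pts[2] == (1.0, pytest.approx(5 / 6), pytest.approx(1.0))
        assert pts[3] == (0.0, pytest.approx(1.0), pytest.approx(1.0))

    def test_efficiency_curve_all_negative_is_degenerate(self):
        pts = efficiency_curve([1, 2], [False, False])
        assert all(p[2] is None for p in pts)

    def test_pr_curve_hand_fixture_and_perfect_classifier(self):
        pts = pr_curve(self.FIXTURE_SCORES, self.FIXTURE_LABELS)
        assert pts[0] == (3.0, pytest.approx(1.0), pytest.approx(2 / 3))
        assert pts[2] == (1.0, pytest.approx(3 / 5), pytest.approx(1.0))
        perfect = pr_curve([0, 0, 9, 9], [False, False, True, True])
        assert perfect[0] == (9.0, pytest.approx(1.0), pytest.approx(1.0))

    def test_pr_precision_matches_prevalence_for_random_scores(self):
        rng = np.random.default_rng(9)
        scores = rng.integers(0, 10, 50_000)
        labels = rng.random(50_000) < 0.05
        pts = pr_curve(scores, labels)
        mid = [p for p in pts if 0.3 < p[2] < 0.9]
        assert all(abs(prec - 0.05) < 0.01 for _, prec, _ in mid)

    def test_roc_curve_reaches_corners_and_is_monotone(self):
        pts = roc_curve_points(self.FIXTURE_SCORES, self.FIXTURE_LABELS)
        fprs = [p[1] for p in pts]
        tprs = [p[2] for p in pts]
        assert fprs == sorted(fprs) and tprs == sorted(tprs)
        assert pts[-1][1:] == (pytest.approx(1.0), pytest.approx(1.0))


class TestEvaluateAndSummaries:
    def test_full_report_is_internally_consistent(self):
        rng = np.random.default_rng(10)
        labels = rng.random(4000) < 0.08
        tte = [float(rng.uniform(0, 24)) if l else None for l in labels]
        scores = rng.integers(0, 15, 4000) + 4 * labels
        rep = evaluate(scores, labels, tte, bootstrap_reps=100, seed=3)
        assert rep.ci_low <= rep.auroc <= rep.ci_high
        assert rep.n_events == labels.sum()
        assert rep.operating_points[0].threshold == 5
        assert rep.auroc_by_window[0][0] == 24.0

    def test_admission_max_aggregation(self):
        ids = ["a", "a", "b", "b", "c"]
        scores = [3, 8, 2, 2, 9]
        labels = [False, True, True, False, False]
        summary = admission_level_summary(ids, scores, labels, threshold=7)
        assert summary["n_admissions"] == 3
        assert summary["n_event_admissions"] == 2
        assert summary["n_identified"] == 1  # only "a" peaks at >= 7

    def test_per_thousand_gains_from_printed_style_points(self):
        a = operating_point([7, 7, 0, 0], [True, False, True, False], 7)
        b = operating_point([7, 7, 7, 0], [True, False, True, False], 7)
        gains = per_thousand_gains(a, b)
        assert gains["extra_detected_events_per_1000_events"] == pytest.approx(500.0)
        with pytest.raises(ValueError):
            per_thousand_gains(a, operating_point([1, 0], [True, False], 1))
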