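"""Metric oracles: every statistic is checked against an exhaustive
brute-force implementation or a hand computation."""


import numpy as np
import pytest

from campnet.evaluation import (PRESET_AGE_CUTS, SingleClassError,
                                apply_platt, average_precision, binary_auc,
                                calibration_curve, evaluate_multilabel,
                                fit_platt, macro_report, subgroup_report,
                                threshold_metrics)


def brute_force_auc(scores, labels):
    """Pairwise Mann–Whitney enumeration."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_ap(scores, labels):
    """Evaluate precision/recall at every distinct threshold directly."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n_pos = labels.sum()
    thresholds = sorted(set(scores), reverse=True)
    ap, prev_recall = 0.0, 0.0
    for t in thresholds:
        pred = scores >= t
        tp = float(np.sum(pred * labels))
        precision = tp / pred.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


class TestBinaryAUC:
    def test_worked_example(self):
        assert binary_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == \
            pytest.approx(0.75)

    def test_perfect_separation(self):
        assert binary_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert binary_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_single_class_raises(self):
        with pytest.raises(SingleClassError):
            binary_auc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_on_200_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(2, 13))
            scores = rng.choice([0.1, 0.25, 0.5, 0.7, 0.9], n)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert binary_auc(scores, labels) == \
                pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        base = binary_auc(scores, labels)
        assert binary_auc(np.exp(3 * scores), labels) == pytest.approx(base)


class TestAveragePrecision:
    def test_perfect_ranking(self):
        assert average_precision([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_worked_example(self):
        ap = average_precision([0.9, 0.8, 0.7], [1, 0, 1])
        assert ap == pytest.approx(0.5 * 1.0 + 0.5 * (2.0 / 3.0), abs=1e-12)

    def test_constant_scores_give_prevalence(self):
        ap = average_precision([0.4] * 10, [1, 0, 0, 1, 0, 0, 0, 0, 0, 1])
        assert ap == pytest.approx(0.3)

    def test_no_positives_raises(self):
        with pytest.raises(SingleClassError):
            average_precision([0.1, 0.2], [0, 0])

    def test_matches_brute_force_on_200_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(2, 13))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], n)
            labels = rng.integers(0, 2, n)
            if labels.sum() == 0:
                labels[0] = 1
            assert average_precision(scores, labels) == \
                pytest.approx(brute_force_ap(scores, labels), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[0] = 1
        base = average_precision(scores, labels)
        assert average_precision(2 * scores + 5, labels) == \
            pytest.approx(base, abs=1e-12)


class TestThresholdMetrics:
    def test_confusion_worked_example(self):
        f1, rec, prec, acc, spec = threshold_metrics([1, 0, 0, 1],
                                                     [1, 0, 1, 0])
        assert (f1, rec, prec, acc, spec) == (0.5, 0.5, 0.5, 0.5, 0.5)

    def test_perfect_predictions(self):
        out = threshold_metrics([0.9, 0.1, 0.8, 0.2], [1, 0, 1, 0])
        assert out == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_all_negative_predictions_fallbacks(self):
        f1, rec, prec, acc, spec = threshold_metrics([0.1, 0.2, 0.3],
                                                     [1, 0, 1])
        assert rec == 0.0 and prec == 0.0 and f1 == 0.0 and spec == 1.0

    def test_specificity_on_flipped_labels_equals_recall(self):
        rng = np.random.default_rng(3)
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        _, rec, _, _, _ = threshold_metrics(scores, labels)
        _, _, _, _, spec = threshold_metrics(1 - scores, 1 - labels, 0.5)
        # flipped scores with flipped labels: predicted positives swap roles
        assert spec == pytest.approx(rec)


class TestMacroReport:
    def test_identical_values_have_zero_sd(self):
        import pandas as pd
        df = pd.DataFrame({"auc": [0.9, 0.9, 0.9]},
                          index=["a", "b", "c"])
        rep = macro_report(df)
        assert rep.macro_mean["auc"] == 0.9 and rep.macro_sd["auc"] == 0.0

    def test_hand_computed_mean_and_population_sd(self):
        import pandas as pd
        df = pd.DataFrame({"auc": [0.8, 0.9]}, index=["a", "b"])
        rep = macro_report(df)
        assert rep.macro_mean["auc"] == pytest.approx(0.85)
        assert rep.macro_sd["auc"] == pytest.approx(0.05)

    def test_undefined_labels_change_the_divisor(self):
        import pandas as pd
        df = pd.DataFrame({"auc": [0.8, np.nan, 0.6]}, index=list("abc"))
        rep = macro_report(df, excluded={"auc": ["b"]})
        assert rep.macro_mean["auc"] == pytest.approx(0.7)

    def test_full_report_on_separable_multilabel_data(self):
        rng = np.random.default_rng(4)
        n = 400
        labels = rng.integers(0, 2, (n, 13))
        probs = np.clip(labels * 0.8 + rng.normal(0, 0.05, (n, 13)) + 0.1,
                        0, 1)
        rep = evaluate_multilabel(probs, labels)
        assert rep.per_label.shape == (13, 7)
        assert rep.macro_mean["auc"] > 0.99
        assert np.all(rep.per_label.to_numpy() <= 1.0 + 1e-12)
        assert np.all(rep.per_label.to_numpy() >= 0.0 - 1e-12)


class TestPlatt:
    def test_recovers_identity_on_calibrated_logistic_data(self):
        rng = np.random.default_rng(5)
        n = 10_000
        logits = rng.normal(0, 2, (n, 1))
        y = (rng.random((n, 1)) < 1 / (1 + np.exp(-logits))).astype(int)
        ab = fit_platt(logits, y)
        assert abs(ab[0, 0] - 1.0) < 0.1
        assert abs(ab[0, 1]) < 0.1

    def test_auc_invariant_under_fitted_monotone_transform(self):
        rng = np.random.default_rng(6)
        n = 2000
        logits = rng.normal(0, 2, (n, 1))
        y = (rng.random((n, 1)) < 1 / (1 + np.exp(-logits))).astype(int)
        ab = fit_platt(logits, y)
        assert ab[0, 0] > 0
        before = binary_auc(logits[:, 0], y[:, 0])
        after = binary_auc(apply_platt(logits, ab)[:, 0], y[:, 0])
        assert after == pytest.approx(before, abs=1e-12)

    def test_constant_logit_offset_absorbed_by_intercept(self):
        rng = np.random.default_rng(7)
        n = 20_000
        logits = rng.normal(0, 2, (n, 1))
        y = (rng.random((n, 1)) < 1 / (1 + np.exp(-logits))).astype(int)
        delta = 1.5
        ab = fit_platt(logits + delta, y)
        # sigma(a*(z+delta)+b) must match sigma(z): b ~= -a*delta
        assert ab[0, 1] == pytest.approx(-ab[0, 0] * delta, abs=0.1)

    def test_single_class_label_skipped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="single class"):
            ab = fit_platt(np.zeros((5, 1)), np.ones((5, 1)))
        assert np.all(np.isnan(ab))


class TestCalibrationCurve:
    def test_bin_counts_partition_the_sample(self):
        rng = np.random.default_rng(8)
        p = rng.random(500)
        y = rng.integers(0, 2, 500)
        curve = calibration_curve(p, y)
        assert curve.counts.sum() == 500

    def test_conserves_total_positives(self):
        rng = np.random.default_rng(9)
        p = rng.random(1000)
        y = (rng.random(1000) < p).astype(int)
        curve = calibration_curve(p, y)
        occupied = curve.counts > 0
        total = np.sum(curve.counts[occupied]
                       * curve.observed_frequency[occupied])
        assert total == pytest.approx(y.sum())

    def test_single_occupied_bin_for_constant_probability(self):
        p = np.full(100, 0.5)
        y = np.r_[np.ones(50), np.zeros(50)]
        curve = calibration_curve(p, y)
        assert (curve.counts > 0).sum() == 1
        occ = np.flatnonzero(curve.counts)[0]
        assert curve.observed_frequency[occ] == pytest.approx(0.5)

    def test_calibrated_by_construction_probabilities_sit_on_diagonal(self):
        rng = np.random.default_rng(10)
        p = rng.random(50_000)
        y = (rng.random(50_000) < p).astype(int)
        curve = calibration_curve(p, y)
        gap = np.nanmax(np.abs(curve.mean_predicted
                               - curve.observed_frequency))
        assert gap < 0.05

    def test_out_of_range_probabilities_rejected(self):
        with pytest.raises(ValueError):
            calibration_curve([1.2], [1])


class TestSubgroups:
    def _data(self, rng, n=200):
        probs = rng.random((n, 13))
        labels = rng.integers(0, 2, (n, 13))
        return probs, labels

    def test_single_sex_cohort_reports_one_empty_group(self, rng):
        probs, labels = self._data(rng)
        rep = subgroup_report(probs, labels, sexes=np.ones(200, int),
                              scheme="sex")
        assert rep.groups["female"] is None
        assert rep.groups["male"] is not None

    def test_uniform_ages_give_quartile_boundaries_by_order_statistics(self,
                                                                       rng):
        probs, labels = self._data(rng, 100)
        ages = np.arange(1.0, 101.0)
        rep = subgroup_report(probs, labels, ages=ages,
                              scheme="age_quartile")
        np.testing.assert_allclose(rep.boundaries, [25.75, 50.5, 75.25])
        assert all(len(idx) == 25 for idx in rep.membership.values())

    def test_fixed_age_cuts_accepted(self, rng):
        probs, labels = self._data(rng, 100)
        ages = np.linspace(20, 95, 100)
        rep = subgroup_report(probs, labels, ages=ages,
                              scheme="age_quartile", age_cuts=PRESET_AGE_CUTS)
        assert rep.boundaries == PRESET_AGE_CUTS

    def test_groups_partition_records(self, rng):
        probs, labels = self._data(rng)
        ages = rng.uniform(20, 90, 200)
        rep = subgroup_report(probs, labels, ages=ages,
                              scheme="age_quartile")
        union = np.sort(np.concatenate(list(rep.membership.values())))
        np.testing.assert_array_equal(union, np.arange(200))
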