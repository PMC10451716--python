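"""Metrics, McNemar, the combined 5x2 cv F-test, and fold aggregation."""

import math
import warnings

import numpy as np
import pytest
from scipy import stats as sps

from patchtest import (
    ConfusionCounts,
    PairedOutcomes,
    aggregate_folds,
    confusion_from_records,
    five_by_two_ftest,
    mcnemar,
    metrics,
    paired_outcomes,
)
from patchtest.classifier import PredictionRecord


def record(key, true, pred):
    return PredictionRecord(key, true, 0.5, pred, np.zeros(2))


class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(tp=50, fp=0, tn=50, fn=0))
        assert all(v == 1.0 for v in m.values())

    def test_hand_arithmetic(self):
        m = metrics(ConfusionCounts(tp=30, fp=10, tn=40, fn=20))
        assert m["recall"] == pytest.approx(0.6)
        assert m["precision"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(2 / 3, abs=1e-9)
        assert m["accuracy"] == pytest.approx(0.7)
        assert m["specificity"] == pytest.approx(0.8)

    def test_no_positives_reports_nan_with_warning(self):
        with pytest.warns(RuntimeWarning):
            m = metrics(ConfusionCounts(tp=0, fp=0, tn=100, fn=0))
        assert m["specificity"] == 1.0 and m["accuracy"] == 1.0
        assert math.isnan(m["recall"]) and math.isnan(m["precision"]) and math.isnan(m["f1"])

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    def test_against_per_record_counting_oracle(self, rng):
        """metrics() over a confusion matrix built from records matches a direct
        per-record tally of the definitions."""
        for _ in range(20):
            n = int(rng.integers(10, 60))
            truth = rng.random(n) < 0.5
            pred = rng.random(n) < 0.5
            recs = [
                record(("p", 1, str(i)), "positive" if t else "negative", "positive" if p else "negative")
                for i, (t, p) in enumerate(zip(truth, pred))
            ]
            counts = confusion_from_records(recs)
            tp = int((truth & pred).sum()); fp = int((~truth & pred).sum())
            fn = int((truth & ~pred).sum()); tn = int((~truth & ~pred).sum())
            assert (counts.tp, counts.fp, counts.tn, counts.fn) == (tp, fp, tn, fn)
            if tp + fn and tp + fp and tp:
                m = metrics(counts)
                assert m["recall"] == pytest.approx(tp / (tp + fn))
                assert m["f1"] == pytest.approx(2 * tp / (2 * tp + fp + fn))


class TestMcNemar:
    def test_symmetric_discordance_gives_p_one(self):
        res = mcnemar(PairedOutcomes(b=5, c=5, n=50), mode="exact")
        assert res.p_value == pytest.approx(1.0)

    def test_one_sided_discordance_closed_form(self):
        res = mcnemar(PairedOutcomes(b=10, c=0, n=50), mode="exact")
        assert res.p_value == pytest.approx(2 * 0.5**10, rel=1e-12)

    def test_chi2_with_continuity_correction(self):
        res = mcnemar(PairedOutcomes(b=40, c=20, n=200), mode="chi2")
        assert res.statistic == pytest.approx((abs(40 - 20) - 1) ** 2 / 60)
        assert res.p_value == pytest.approx(float(sps.chi2.sf(res.statistic, 1)), rel=1e-12)
        assert res.p_value == pytest.approx(0.0142, abs=5e-4)

    def test_auto_mode_switches_at_25_discordant(self):
        assert mcnemar(PairedOutcomes(10, 10, 100)).method == "mcnemar-exact"
        assert mcnemar(PairedOutcomes(15, 15, 100)).method == "mcnemar-chi2"

    def test_no_discordance_convention(self):
        with pytest.warns(RuntimeWarning):
            res = mcnemar(PairedOutcomes(0, 0, 30))
        assert res.p_value == 1.0

    def test_exact_agrees_with_binomial_enumeration(self):
        """Exact-mode p matches direct pmf enumeration to 1e-12 for all b+c <= 30."""
        for n_disc in range(1, 31):
            for b in range(n_disc + 1):
                res = mcnemar(PairedOutcomes(b, n_disc - b, 100), mode="exact")
                pmf = np.array([math.comb(n_disc, k) * 0.5**n_disc for k in range(n_disc + 1)])
                p_two = float(pmf[pmf <= pmf[b] * (1 + 1e-12)].sum())
                assert res.p_value == pytest.approx(min(1.0, p_two), abs=1e-12)

    def test_paired_outcomes_alignment(self):
        a = [record(("p", 1, "x"), "positive", "positive"), record(("p", 1, "y"), "negative", "positive")]
        b = [record(("p", 1, "y"), "negative", "negative"), record(("p", 1, "x"), "positive", "negative")]
        out = paired_outcomes(a, b)
        assert (out.b, out.c, out.n) == (1, 1, 2)

    def test_paired_outcomes_rejects_mismatched_chambers(self):
        a = [record(("p", 1, "x"), "positive", "positive")]
        b = [record(("p", 1, "z"), "positive", "positive")]
        with pytest.raises(ValueError):
            paired_outcomes(a, b)


class TestFiveByTwo:
    def test_alternating_differences_give_half(self):
        """p_ij = +-delta within each repetition: F = 10 d^2 / (2 * 5 * 2 d^2) = 0.5."""
        d = 0.3
        diffs = np.array([[d, -d]] * 5)
        res = five_by_two_ftest(diffs)
        assert res.statistic == pytest.approx(0.5, rel=1e-12)
        assert res.p_value == pytest.approx(float(sps.f.sf(0.5, 10, 5)), rel=1e-12)

    def test_constant_differences_degenerate(self):
        with pytest.warns(RuntimeWarning):
            res = five_by_two_ftest(np.full((5, 2), 0.2))
        assert math.isnan(res.p_value)

    def test_shape_validated(self):
        with pytest.raises(ValueError):
            five_by_two_ftest(np.zeros((4, 2)))

    def test_large_effect_vs_noise(self, rng):
        noise = rng.normal(0, 0.01, size=(5, 2))
        assert five_by_two_ftest(noise + 0.3).p_value < 0.05
        assert five_by_two_ftest(noise).p_value > 0.05


class TestAggregate:
    def test_identical_folds_have_zero_sd(self):
        table, _ = aggregate_folds([{"f1": 0.8}, {"f1": 0.8}, {"f1": 0.8}])
        assert table.loc[0, "sd"] == pytest.approx(0.0, abs=1e-12)

    def test_sample_sd_two_folds(self):
        table, _ = aggregate_folds([{"f1": 0.8}, {"f1": 0.9}])
        assert table.loc[0, "mean"] == pytest.approx(0.85)
        assert table.loc[0, "sd"] == pytest.approx(0.0707, abs=1e-4)

    def test_confusions_summed(self):
        folds = [ConfusionCounts(1, 2, 3, 4), ConfusionCounts(10, 20, 30, 40)]
        _, pooled = aggregate_folds([{"f1": 0.5}, {"f1": 0.5}], folds)
        assert (pooled.tp, pooled.fp, pooled.tn, pooled.fn) == (11, 22, 33, 44)

    def test_fold_count_mismatch(self):
        with pytest.raises(ValueError):
            aggregate_folds([{"f1": 0.5}], [ConfusionCounts(1, 1, 1, 1)])
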