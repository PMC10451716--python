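"""Training loop, schedule, prediction records, and the allergen Z-report."""

import numpy as np
import pandas as pd
import pytest

from patchtest import (
    BACKBONES,
    TrainConfig,
    allergen_error_zscores,
    build_dataset,
    cosine_lr,
    make_split,
    predict,
    train,
)
from patchtest.classifier import PredictionRecord
from patchtest.stats import confusion_from_records, metrics


@pytest.fixture(scope="module")
def trained(separable_cohort):
    """One reduced-profile model on the separable cohort, shared by read-only tests."""
    plan = make_split(separable_cohort.manifest, "holdout_70_30", seed=0)
    ds = build_dataset(separable_cohort, separable_cohort.manifest, "crop", "redness", transform_size=64)
    config = TrainConfig.reduced(epochs=15, seed=0)
    model = train(ds, plan, config)
    return ds, plan, model


class TestSchedule:
    def test_endpoints(self):
        assert cosine_lr(0, 250, 3e-4, 1e-5) == pytest.approx(3e-4)
        assert cosine_lr(249, 250, 3e-4, 1e-5) == pytest.approx(1e-5)

    def test_closed_form_matches_log(self, trained):
        _, _, model = trained
        lr_start, lr_end, total = model.config.lr_start, model.config.lr_end, model.config.epochs
        for row in model.log.itertuples():
            expected = lr_end + (lr_start - lr_end) * (1 + np.cos(np.pi * row.epoch / (total - 1))) / 2
            assert row.lr == pytest.approx(expected, abs=1e-12)

    def test_monotone_decreasing(self):
        lrs = [cosine_lr(t, 100, 3e-4, 1e-5) for t in range(100)]
        assert all(a > b for a, b in zip(lrs, lrs[1:]))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_start=1e-5, lr_end=3e-4)
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)


class TestTraining:
    def test_seeded_determinism(self, separable_cohort):
        plan = make_split(separable_cohort.manifest, "holdout_70_30", seed=0)
        ds = build_dataset(separable_cohort, separable_cohort.manifest, "crop", "redness", transform_size=64)
        config = TrainConfig.reduced(epochs=5, seed=11)
        r1 = predict(train(ds, plan, config), ds, plan)
        r2 = predict(train(ds, plan, config), ds, plan)
        assert [r.predicted_label for r in r1] == [r.predicted_label for r in r2]
        assert np.allclose([r.score for r in r1], [r.score for r in r2])

    def test_separable_phantom_reaches_high_f1(self, trained):
        """On a none-vs-extreme cohort the reduced profile should be near-perfect."""
        ds, plan, model = trained
        recs = predict(model, ds, plan)
        assert metrics(confusion_from_records(recs))["f1"] > 0.9

    def test_leakage_guard_fires(self, separable_cohort):
        plan = make_split(separable_cohort.manifest, "holdout_70_30", seed=0)
        ds = build_dataset(separable_cohort, separable_cohort.manifest, "crop", "redness", transform_size=64)
        plan.assignments[(0, "val")] = plan.assignments[(0, "train")][:1] + plan.assignments[(0, "val")][1:]
        with pytest.raises(RuntimeError, match="leakage"):
            train(ds, plan, TrainConfig.reduced(epochs=1))

    def test_loss_log_one_row_per_epoch(self, trained):
        _, _, model = trained
        assert list(model.log["epoch"]) == list(range(model.config.epochs))
        assert model.log["loss"].iloc[-1] < model.log["loss"].iloc[0]


class TestPredict:
    def test_one_record_per_validation_chamber(self, trained):
        ds, plan, model = trained
        recs = predict(model, ds, plan)
        _, val_patients = plan.train_val()
        expected = sum(1 for p in ds.patient_ids if p in val_patients)
        assert len(recs) == expected

    def test_scores_in_unit_interval(self, trained):
        ds, plan, model = trained
        assert all(0.0 <= r.score <= 1.0 for r in predict(model, ds, plan))

    def test_feature_width_matches_backbone_metadata(self, trained):
        ds, plan, model = trained
        recs = predict(model, ds, plan)
        assert all(len(r.feature_vector) == model.feature_width for r in recs)
        assert model.feature_width == BACKBONES[model.config.backbone].feature_width

    def test_default_backbone_penultimate_width(self):
        assert BACKBONES["pooled-mlp-1280"].feature_width == 1280

    def test_threshold_rule(self, trained):
        ds, plan, model = trained
        for r in predict(model, ds, plan):
            assert r.predicted_label == ("positive" if r.score >= 0.5 else "negative")


class TestAllergenZscores:
    def make_records(self, error_pcts, n_per=10):
        recs = []
        for i, pct in enumerate(error_pcts):
            n_wrong = round(n_per * pct / 100)
            for j in range(n_per):
                correct = j >= n_wrong
                recs.append(
                    PredictionRecord(
                        (f"p{j}", 1, f"allergen{i}"), "positive",
                        0.9, "positive" if correct else "negative", np.zeros(2),
                    )
                )
        return recs

    def test_zero_variance_convention(self):
        out = allergen_error_zscores(self.make_records([10, 10, 10]))
        assert (out["z"] == 0).all() and not out["outlier"].any()

    def test_single_high_error_allergen(self):
        """Nine allergens at 10% plus one at 90%: population-sd Z of the outlier
        is exactly 3.0, which the strict |Z| > 3 rule does not flag."""
        out = allergen_error_zscores(self.make_records([10] * 9 + [90]))
        z = out.set_index("allergen_id")["z"]
        assert z["allergen9"] == pytest.approx(3.0, abs=1e-9)
        assert not out["outlier"].any()

    def test_extreme_outlier_flagged(self):
        out = allergen_error_zscores(self.make_records([10] * 15 + [90]))
        assert out.set_index("allergen_id")["outlier"]["allergen15"]

    def test_requires_three_allergens(self):
        with pytest.raises(ValueError):
            allergen_error_zscores(self.make_records([10, 20]))

    def test_pools_counts_over_folds(self):
        # same allergen appearing in two "folds": errors pooled, not averaged
        recs = self.make_records([0, 50, 100], n_per=4) + self.make_records([100, 50, 0], n_per=4)
        out = allergen_error_zscores(recs).set_index("allergen_id")
        assert (out["error_pct"] == 50.0).all()
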