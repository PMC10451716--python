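"""Train the binary reaction classifier on one modality and report metrics.

Uses a small, well-separated phantom (none vs extreme reactions) with the
desk-scale training profile; the patient-grouped 70/30 split guarantees no
patient appears on both sides.
"""

from patchtest import (
    PhantomConfig,
    TrainConfig,
    build_dataset,
    generate_cohort,
    make_split,
    predict,
    train,
)
from patchtest.stats import confusion_from_records, metrics

cohort = generate_cohort(
    PhantomConfig(
        n_patients=14, chambers_per_area=4, image_size=96, chamber_size=28,
        grade_probabilities=(0.5, 0.0, 0.0, 0.5), seed=7,
    )
)
plan = make_split(cohort.manifest, "holdout_70_30", seed=0)
dataset = build_dataset(cohort, cohort.manifest, "am", "redness", transform_size=64)

model = train(dataset, plan, TrainConfig.reduced(epochs=15, seed=0))
records = predict(model, dataset, plan)

counts = confusion_from_records(records)
print(f"validation chambers: {counts.total}  (tp={counts.tp} fp={counts.fp} tn={counts.tn} fn={counts.fn})")
for name, value in metrics(counts).items():
    print(f"  {name:12s} {value:.3f}")
print()
print("On a cohort where reactions are either absent or extreme, the reduced")
print("profile separates the classes almost perfectly; learning-rate log:")
print(f"  epoch 0 lr = {model.log.lr.iloc[0]:.1e}, final lr = {model.log.lr.iloc[-1]:.1e} (cosine annealing)")
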