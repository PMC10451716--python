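"""End-to-end drivers for the three analyses.

1. **Pre-processing comparison** — train one classifier per scheme
   (crop / am / ceam) on a single modality with one shared patient-grouped
   70/30 split, report the five metrics per scheme and pairwise McNemar
   tests on the common validation chambers.
2. **Modality comparison** — train per modality with patient-grouped 5-fold
   cross-validation (mean +- sd metrics, pooled confusion matrices), run
   pairwise McNemar tests on an additional 70/30 split, and rank allergens
   by pooled false-prediction percentage with Z-score outlier flags.
3. **Fusion investigation** — extract penultimate features of the 70/30
   validation chambers from each modality's model, summarize pairwise
   feature redundancy (mean +- sd of absolute per-chamber Pearson r), and
   evaluate fused pairs with an RBF-SVM under patient-grouped 5x2
   cross-validation, comparing each pair against the single-modality
   baseline with the combined 5x2 cv F-test.

All drivers are plain functions over in-memory cohorts so they compose from
Python; ``outdir`` writes CSV tables plus a JSON provenance record.
"""

from __future__ import annotations

import itertools
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classifier import (
    PredictionRecord,
    TrainConfig,
    allergen_error_zscores,
    build_dataset,
    predict,
    train,
)
from .fusion import ModalityFeatures, fuse_and_classify, pairwise_feature_correlation
from .manifest import SplitPlan, make_split
from .phantom import MODALITIES, NEGATIVE, POSITIVE, Cohort, grade_to_binary
from .stats import (
    ConfusionCounts,
    aggregate_folds,
    confusion_from_records,
    five_by_two_ftest,
    mcnemar,
    metrics,
    paired_outcomes,
)

SCHEMES = ("crop", "am", "ceam")


@dataclass
class ExperimentResult:
    name: str
    tables: dict[str, pd.DataFrame]
    records: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for key, df in self.tables.items():
            df.to_csv(outdir / f"{self.name}_{key}.csv", index=False)
        (outdir / f"{self.name}_provenance.json").write_text(json.dumps(self.provenance, indent=2, default=str))
        return outdir


def _provenance(seed: int, config: TrainConfig, extra: dict | None = None) -> dict:
    rec = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": seed,
        "train_config": asdict(config),
    }
    rec.update(extra or {})
    return rec


def run_experiment_1(
    cohort: Cohort,
    train_config: TrainConfig,
    modality: str = "color",
    schemes: Sequence[str] = SCHEMES,
    seed: int = 0,
    context_rows: int = 75,
    transform_size: int = 224,
) -> ExperimentResult:
    """Pre-processing scheme comparison on one modality, shared 70/30 split.

    The default modality is color; the comparison is indifferent to the
    choice, and any of the six can be passed.
    """
    plan = make_split(cohort.manifest, "holdout_70_30", seed)
    records: dict[str, list[PredictionRecord]] = {}
    metric_rows = []
    for scheme in schemes:
        ds = build_dataset(cohort, cohort.manifest, scheme, modality, context_rows=context_rows, transform_size=transform_size)
        model = train(ds, plan, train_config)
        recs = predict(model, ds, plan)
        records[scheme] = recs
        m = metrics(confusion_from_records(recs))
        metric_rows.append({"scheme": scheme, **m})
    pair_rows = []
    for a, b in itertools.combinations(schemes, 2):
        res = mcnemar(paired_outcomes(records[a], records[b]))
        pair_rows.append(
            {"comparison": f"{a} vs {b}", "statistic": res.statistic, "p_value": res.p_value,
             "b": res.evidence.b, "c": res.evidence.c, "method": res.method}
        )
    tables = {"metrics": pd.DataFrame(metric_rows), "mcnemar": pd.DataFrame(pair_rows)}
    prov = _provenance(seed, train_config, {"experiment": "preprocessing_comparison", "modality": modality,
                                            "schemes": list(schemes), "split": json.loads(plan.to_json())})
    return ExperimentResult("experiment1", tables, {"records": records, "plan": plan}, prov)


def run_experiment_2(
    cohort: Cohort,
    train_config: TrainConfig,
    scheme: str = "ceam",
    modalities: Sequence[str] = MODALITIES,
    seed: int = 0,
    context_rows: int = 75,
    transform_size: int = 224,
) -> ExperimentResult:
    """Per-modality 5-fold CV metrics, pairwise McNemar on 70/30, Z-report."""
    kplan = make_split(cohort.manifest, "kfold_5", seed)
    hplan = make_split(cohort.manifest, "holdout_70_30", seed)

    metric_rows, pooled_rows = [], []
    holdout_records: dict[str, list[PredictionRecord]] = {}
    cv_records: dict[str, list[PredictionRecord]] = {}
    models = {}
    for modality in modalities:
        ds = build_dataset(cohort, cohort.manifest, scheme, modality, context_rows=context_rows, transform_size=transform_size)
        fold_metrics, fold_counts, pooled_recs = [], [], []
        for fold in range(5):
            model = train(ds, kplan, train_config, fold=fold)
            recs = predict(model, ds, kplan, fold=fold)
            fold_counts.append(confusion_from_records(recs))
            fold_metrics.append(metrics(fold_counts[-1]))
            pooled_recs.extend(recs)
        agg, pooled = aggregate_folds(fold_metrics, fold_counts)
        for row in agg.itertuples():
            metric_rows.append({"modality": modality, "metric": row.metric, "mean": row.mean, "sd": row.sd})
        pooled_rows.append({"modality": modality, "tp": pooled.tp, "fp": pooled.fp, "tn": pooled.tn, "fn": pooled.fn})
        cv_records[modality] = pooled_recs
        # additional 70/30 model for the paired tests and feature extraction
        model = train(ds, hplan, train_config)
        holdout_records[modality] = predict(model, ds, hplan)
        models[modality] = model

    pair_rows = []
    for a, b in itertools.combinations(modalities, 2):
        res = mcnemar(paired_outcomes(holdout_records[a], holdout_records[b]))
        pair_rows.append({"comparison": f"{a} vs {b}", "statistic": res.statistic, "p_value": res.p_value,
                          "b": res.evidence.b, "c": res.evidence.c, "method": res.method})

    z_frames = []
    for modality in modalities:
        z = allergen_error_zscores(cv_records[modality])
        z.insert(0, "modality", modality)
        z_frames.append(z)

    tables = {
        "metrics": pd.DataFrame(metric_rows),
        "pooled_confusions": pd.DataFrame(pooled_rows),
        "mcnemar": pd.DataFrame(pair_rows),
        "allergen_zscores": pd.concat(z_frames, ignore_index=True),
    }
    prov = _provenance(seed, train_config, {"experiment": "modality_comparison", "scheme": scheme,
                                            "modalities": list(modalities)})
    return ExperimentResult(
        "experiment2", tables,
        {"holdout_records": holdout_records, "cv_records": cv_records, "models": models, "holdout_plan": hplan},
        prov,
    )


def _f1_of(records: Sequence[PredictionRecord]) -> float:
    return metrics(confusion_from_records(records))["f1"]


def five_by_two_fused_f1(
    features: dict[str, ModalityFeatures],
    labels: dict[tuple, str],
    combo: tuple[str, ...],
    plan: SplitPlan,
    c_param: float = 3.5,
    seed: int = 0,
) -> np.ndarray:
    """F1 of a modality combo over the 10 (repetition, fold) evaluations.

    ``combo`` is a single modality (SVM on its features alone) or a pair
    (concatenated features).  The supplied 5x2 plan fixes the
    patient-grouped splits, so different combos share folds and their
    per-fold differences feed the combined F-test.
    """
    a = features[combo[0]]
    b = features[combo[1]] if len(combo) == 2 else features[combo[0]]
    keys = a.keys
    patient_of = {k: k[0] for k in keys}
    out = np.zeros((5, 2))
    for rep in range(5):
        for fold in range(2):
            tr_p, va_p = plan.train_val(rep, fold)
            tr = [k for k in keys if patient_of[k] in tr_p]
            va = [k for k in keys if patient_of[k] in va_p]
            if len(combo) == 2:
                _, recs = fuse_and_classify(a, b, labels, tr, va, c_param=c_param, seed=seed)
            else:
                _, recs = fuse_and_classify(a, a, labels, tr, va, c_param=c_param, seed=seed)
            out[rep, fold] = _f1_of(recs)
    return out


def run_experiment_3(
    holdout_records: dict[str, list[PredictionRecord]],
    modalities: Sequence[str] | None = None,
    baseline: str = "color",
    c_param: float = 3.5,
    seed: int = 0,
) -> ExperimentResult:
    """Feature redundancy and pairwise fusion on the validation chambers.

    ``holdout_records`` are the per-modality validation predictions of the
    70/30 models (e.g. from :func:`run_experiment_2`); their feature vectors
    and labels drive everything here, so no re-training of the networks is
    involved.
    """
    modalities = list(modalities or holdout_records)
    features = {m: ModalityFeatures.from_records(m, holdout_records[m]) for m in modalities}
    labels = {r.key: r.true_label for r in holdout_records[modalities[0]]}

    corr_rows = []
    for a, b in itertools.combinations(modalities, 2):
        cs = pairwise_feature_correlation(features[a], features[b])
        corr_rows.append({"pair": f"{a} + {b}", "mean_abs_r": cs.mean_abs_r, "sd_abs_r": cs.sd_abs_r,
                          "n_chambers": cs.n_chambers})

    # patient-grouped 5x2 CV over the validation chambers
    val_manifest = pd.DataFrame({"patient_id": sorted({k[0] for k in features[modalities[0]].keys})})
    plan = make_split(val_manifest, "five_by_two", seed)

    combos: list[tuple[str, ...]] = [(baseline,)] + [tuple(p) for p in itertools.combinations(modalities, 2)]
    f1_grids = {c: five_by_two_fused_f1(features, labels, c, plan, c_param, seed) for c in combos}
    f1_rows = [
        {"combo": " + ".join(c), "f1_mean": float(g.mean()), "f1_sd": float(g.std(ddof=1))}
        for c, g in f1_grids.items()
    ]

    ftest_rows = []
    base_grid = f1_grids[(baseline,)]
    for c in combos[1:]:
        res = five_by_two_ftest(f1_grids[c] - base_grid)
        ftest_rows.append({"comparison": f"{baseline} vs {' + '.join(c)}",
                           "F": res.statistic, "p_value": res.p_value})

    tables = {
        "correlations": pd.DataFrame(corr_rows),
        "f1_5x2": pd.DataFrame(f1_rows),
        "ftest": pd.DataFrame(ftest_rows),
    }
    prov = {
        "package_version": __version__,
        "experiment": "fusion_investigation",
        "baseline": baseline,
        "modalities": modalities,
        "c_param": c_param,
        "seed": seed,
    }
    return ExperimentResult("experiment3", tables, {"f1_grids": f1_grids, "plan": plan}, prov)
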