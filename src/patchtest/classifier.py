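"""Binary reaction classifier per modality and pre-processing scheme.

The classifier is a compact fully connected network operating on
block-pooled, ImageNet-normalized image tensors.  The training machinery
follows the study protocol for fine-tuning: AdamW, a cosine-annealed
learning rate from 3e-4 down to 1e-5, batch size 8, seeded flip/rotation
augmentation, and sigmoid output on the positive class.  The layer
preceding the final fully connected classifier (the penultimate layer) is
exposed as the learned feature representation, which the fusion stage
consumes.

Two backbones are registered:

* ``pooled-mlp-1280`` (default) — 14x14 block pooling, one 1280-unit hidden
  layer (penultimate width 1280, the width typical of compact
  image-classification backbones);
* ``pooled-mlp-tiny`` — 8x8 pooling and a 128-unit penultimate layer, a
  desk-scale profile that trains in seconds on small phantoms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .manifest import SplitPlan
from .phantom import Cohort, grade_to_binary, NEGATIVE, POSITIVE
from .preprocess import IMAGENET_MEAN, IMAGENET_STD, PreprocessedSample, model_transform, preprocess


@dataclass(frozen=True)
class BackboneSpec:
    name: str
    pool: int  # pooled spatial grid (pool x pool per channel)
    hidden: tuple[int, ...]  # hidden-layer widths; last entry is the penultimate layer

    @property
    def input_width(self) -> int:
        # pooled grid plus its 3x3 center-surround contrast, 3 channels each
        return 2 * 3 * self.pool * self.pool

    @property
    def feature_width(self) -> int:
        return self.hidden[-1]


BACKBONES = {
    "pooled-mlp-1280": BackboneSpec("pooled-mlp-1280", pool=14, hidden=(1280,)),
    "pooled-mlp-tiny": BackboneSpec("pooled-mlp-tiny", pool=8, hidden=(256, 128)),
}


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters.

    Defaults follow the full protocol (250 epochs, batch 8, AdamW with
    cosine annealing 3e-4 -> 1e-5, flip/rotation augmentation);
    :meth:`reduced` returns a desk-scale profile for experimentation and
    continuous testing.
    """

    backbone: str = "pooled-mlp-1280"
    epochs: int = 250
    batch_size: int = 8
    lr_start: float = 3e-4
    lr_end: float = 1e-5
    weight_decay: float = 0.01
    augment: bool = True
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.lr_start > self.lr_end > 0):
            raise ValueError("need lr_start > lr_end > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone: {self.backbone!r}")

    @classmethod
    def reduced(cls, epochs: int = 30, seed: int = 0, **overrides) -> "TrainConfig":
        """Desk-scale profile: tiny backbone, few epochs, no augmentation."""
        return cls(backbone="pooled-mlp-tiny", epochs=epochs, augment=False, seed=seed, **overrides)


def cosine_lr(epoch: int, total_epochs: int, lr_start: float, lr_end: float) -> float:
    """Cosine-annealed learning rate; epoch 0 gives ``lr_start``, the final
    epoch gives ``lr_end`` exactly."""
    if total_epochs == 1:
        return lr_start
    t = epoch / (total_epochs - 1)
    return lr_end + (lr_start - lr_end) * (1.0 + math.cos(math.pi * t)) / 2.0


@dataclass
class PredictionRecord:
    """Per-chamber ground truth, score, decision, and learned features."""

    key: tuple[str, int, str]  # (patient_id, area_index, allergen_id)
    true_label: str
    score: float
    predicted_label: str
    feature_vector: np.ndarray

    @property
    def patient_id(self) -> str:
        return self.key[0]

    @property
    def allergen_id(self) -> str:
        return self.key[2]

    @property
    def correct(self) -> bool:
        return self.true_label == self.predicted_label


def records_to_frame(records: Sequence[PredictionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [r.key[0] for r in records],
            "area_index": [r.key[1] for r in records],
            "allergen_id": [r.key[2] for r in records],
            "true_label": [r.true_label for r in records],
            "score": [r.score for r in records],
            "predicted_label": [r.predicted_label for r in records],
        }
    )


# ---------------------------------------------------------------------------
# dataset


@dataclass
class ChamberDataset:
    """Pre-processed chamber samples for one (scheme, modality) pair.

    Eval-mode tensors are computed once and cached; train-mode augmentation
    re-runs the seeded transform on the stored scheme-processed images.
    """

    scheme: str
    modality: str
    keys: list[tuple[str, int, str]]
    patient_ids: list[str]
    labels: np.ndarray  # 1.0 positive / 0.0 negative
    samples: list[PreprocessedSample]
    transform_size: int = 224
    _eval_cache: np.ndarray | None = field(default=None, repr=False)
    _pool_cache: dict = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.keys)

    def eval_tensors(self) -> np.ndarray:
        if self._eval_cache is None:
            self._eval_cache = np.stack(
                [model_transform(s, train_mode=False, out_size=self.transform_size) for s in self.samples]
            )
        return self._eval_cache

    def eval_pooled(self, pool: int) -> np.ndarray:
        if pool not in self._pool_cache:
            self._pool_cache[pool] = _pool_tensors(self.eval_tensors(), pool)
        return self._pool_cache[pool]

    def train_pooled(self, indices: np.ndarray, pool: int, augment: bool, rng: np.random.Generator) -> np.ndarray:
        if not augment:
            return self.eval_pooled(pool)[indices]
        batch = np.stack(
            [model_transform(self.samples[i], train_mode=True, rng=rng, out_size=self.transform_size) for i in indices]
        )
        return _pool_tensors(batch, pool)

    def indices_for(self, patients: set[str]) -> np.ndarray:
        return np.array([i for i, p in enumerate(self.patient_ids) if p in patients], dtype=int)


def build_dataset(
    cohort: Cohort,
    manifest: pd.DataFrame,
    scheme: str,
    modality: str,
    context_rows: int = 75,
    background_alpha: float = 0.5,
    transform_size: int = 224,
) -> ChamberDataset:
    """Assemble one scheme-processed sample per manifest row.

    For CEAM the adjacent capture area of the same patient supplies the
    context strip (area 2 for an area-1 image and vice versa).
    ``transform_size`` sets the model-transform output resolution; 224 is
    the full protocol, smaller powers of the pool grid (e.g. 112) suit
    desk-scale phantoms.
    """
    from .geometry import Roi

    keys, patients, labels, samples = [], [], [], []
    for row in manifest.itertuples():
        pid, area = str(row.patient_id), int(row.area_index)
        cap = cohort.capture(pid, area)
        roi = Roi(int(row.x0), int(row.y0), int(row.x1), int(row.y1))
        image = cap.images[modality]
        adjacent = None
        if scheme == "ceam":
            adjacent = cohort.capture(pid, 3 - area).images[modality]
        sample = preprocess(
            scheme,
            image,
            roi,
            adjacent_image=adjacent,
            area_index=area,
            context_rows=context_rows,
            background_alpha=background_alpha,
            source_id=(pid, area, str(row.allergen_id)),
        )
        keys.append((pid, area, str(row.allergen_id)))
        patients.append(pid)
        labels.append(1.0 if grade_to_binary(str(row.grade)) == POSITIVE else 0.0)
        samples.append(sample)
    return ChamberDataset(scheme, modality, keys, patients, np.asarray(labels), samples, transform_size)


# ---------------------------------------------------------------------------
# model


def _saliency_centers(tensors: np.ndarray) -> np.ndarray:
    """Locate the highlighted region of each image from brightness alone.

    Alpha-masked samples keep the ROI at full brightness while dimming all
    context, so the smoothed-brightness maximum sits inside the ROI; for
    crop samples (no dimmed context) it lands on the reaction or the image
    center, which is equally serviceable.  Returns (n, 2) row/col centers.
    """
    from scipy.ndimage import gaussian_filter

    n, _, s, _ = tensors.shape
    # undo the channel normalization so brightness is physical
    bright = (tensors * IMAGENET_STD[None, :, None, None] + IMAGENET_MEAN[None, :, None, None]).mean(axis=1)
    centers = np.empty((n, 2), dtype=int)
    for i in range(n):
        sm = gaussian_filter(bright[i], sigma=s / 14.0, mode="nearest")
        centers[i] = np.unravel_index(int(np.argmax(sm)), sm.shape)
    return centers


def _pool_tensors(tensors: np.ndarray, pool: int) -> np.ndarray:
    """Featurize a (n, 3, S, S) batch: anchored pooled grid + local contrast.

    Each image is first translated so its brightest (highlighted) region
    sits at the center — the pooled representation is then expressed in
    ROI-relative coordinates, like the translation invariance a
    convolutional feature extractor provides.  Each channel is
    block-averaged to a ``pool x pool`` grid; alongside the raw grid, a
    center-surround map (cell minus its 3x3 neighborhood mean, edge-padded)
    encodes how each region differs from its immediate context — the cue
    that distinguishes a reaction confined to the ROI from erythema
    spilling over from a neighboring chamber.  Output is
    ``(n, 6 * pool * pool)``.
    """
    n, c, s, _ = tensors.shape
    if s % pool:
        raise ValueError(f"image size {s} not divisible by pool {pool}")
    centers = _saliency_centers(tensors)
    half = s // 2
    shifted = np.empty_like(tensors)
    padded = np.pad(tensors, ((0, 0), (0, 0), (half, half), (half, half)), mode="edge")
    for i, (cy, cx) in enumerate(centers):
        shifted[i] = padded[i, :, cy : cy + s, cx : cx + s]
    b = s // pool
    grid = shifted.reshape(n, c, pool, b, pool, b).mean(axis=(3, 5))
    pad = np.pad(grid, ((0, 0), (0, 0), (1, 1), (1, 1)), mode="edge")
    surround = sum(pad[:, :, i : i + pool, j : j + pool] for i in range(3) for j in range(3)) / 9.0
    feats = np.concatenate([grid.reshape(n, -1), (grid - surround).reshape(n, -1)], axis=1)
    return feats.astype(np.float64)


class TrainedModel:
    """A fitted network: weights, the backbone spec, and the training log."""

    def __init__(self, spec: BackboneSpec, config: TrainConfig, weights: list, biases: list, log: pd.DataFrame):
        self.spec = spec
        self.config = config
        self.weights = weights
        self.biases = biases
        self.log = log

    @property
    def feature_width(self) -> int:
        return self.spec.feature_width

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (penultimate features, positive-class scores)."""
        h = x
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ w + b, 0.0)
        logits = (h @ self.weights[-1] + self.biases[-1]).ravel()
        return h, 1.0 / (1.0 + np.exp(-logits))


def _init_params(rng: np.random.Generator, dims: list[int]) -> tuple[list, list]:
    weights, biases = [], []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        weights.append(rng.normal(0.0, math.sqrt(2.0 / d_in), size=(d_in, d_out)))
        biases.append(np.zeros(d_out))
    return weights, biases


def _leakage_guard(train_patients: set[str], val_patients: set[str]) -> None:
    leaked = train_patients & val_patients
    if leaked:
        raise RuntimeError(f"patient leakage between train and validation: {sorted(leaked)[:5]}")


def train(
    dataset: ChamberDataset,
    plan: SplitPlan,
    config: TrainConfig,
    repetition: int = 0,
    fold: int = 0,
) -> TrainedModel:
    """Fit the classifier on the plan's training side.

    Patient disjointness between the two sides is asserted before fitting.
    Fully deterministic given ``config.seed``: the same seed, config and
    data reproduce the fitted weights bit for bit.
    """
    train_patients, val_patients = plan.train_val(repetition, fold)
    _leakage_guard(train_patients, val_patients)
    idx = dataset.indices_for(train_patients)
    if idx.size == 0:
        raise ValueError("empty training side")

    spec = BACKBONES[config.backbone]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, repetition, fold]))
    y = dataset.labels[idx]

    dims = [spec.input_width, *spec.hidden, 1]
    weights, biases = _init_params(rng, dims)
    params = weights + biases
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    log_rows = []
    for epoch in range(config.epochs):
        lr = cosine_lr(epoch, config.epochs, config.lr_start, config.lr_end)
        x_epoch = dataset.train_pooled(idx, spec.pool, config.augment, rng)
        order = rng.permutation(idx.size)
        losses = []
        for start in range(0, idx.size, config.batch_size):
            sel = order[start : start + config.batch_size]
            xb, yb = x_epoch[sel], y[sel]
            # forward
            acts = [xb]
            h = xb
            pre = []
            for w_, b_ in zip(weights[:-1], biases[:-1]):
                z = h @ w_ + b_
                pre.append(z)
                h = np.maximum(z, 0.0)
                acts.append(h)
            logits = (h @ weights[-1] + biases[-1]).ravel()
            p = 1.0 / (1.0 + np.exp(-logits))
            p_c = np.clip(p, 1e-12, 1.0 - 1e-12)
            losses.append(float(-np.mean(yb * np.log(p_c) + (1 - yb) * np.log(1 - p_c))))
            # backward
            g = ((p - yb) / len(yb))[:, None]
            grads_w = [None] * len(weights)
            grads_b = [None] * len(biases)
            grads_w[-1] = acts[-1].T @ g
            grads_b[-1] = g.sum(axis=0)
            dh = g @ weights[-1].T
            for layer in range(len(weights) - 2, -1, -1):
                dz = dh * (pre[layer] > 0)
                grads_w[layer] = acts[layer].T @ dz
                grads_b[layer] = dz.sum(axis=0)
                if layer:
                    dh = dz @ weights[layer].T
            # AdamW update (decoupled weight decay on weights only)
            step += 1
            grads = grads_w + grads_b
            for k, (p_arr, g_arr) in enumerate(zip(params, grads)):
                m[k] = beta1 * m[k] + (1 - beta1) * g_arr
                v[k] = beta2 * v[k] + (1 - beta2) * g_arr**2
                mhat = m[k] / (1 - beta1**step)
                vhat = v[k] / (1 - beta2**step)
                decay = config.weight_decay if k < len(weights) else 0.0
                p_arr -= lr * (mhat / (np.sqrt(vhat) + eps) + decay * p_arr)
        log_rows.append({"epoch": epoch, "lr": lr, "loss": float(np.mean(losses))})

    return TrainedModel(spec, config, weights, biases, pd.DataFrame(log_rows))


def predict(
    model: TrainedModel,
    dataset: ChamberDataset,
    plan: SplitPlan,
    repetition: int = 0,
    fold: int = 0,
    role: str = "val",
) -> list[PredictionRecord]:
    """Score every chamber on the requested side of the split.

    Uses the eval-mode transform (no augmentation); penultimate features are
    captured in the same forward pass as the scores.
    """
    train_patients, val_patients = plan.train_val(repetition, fold)
    patients = val_patients if role == "val" else train_patients
    idx = dataset.indices_for(patients)
    x = dataset.eval_pooled(model.spec.pool)[idx]
    features, scores = model.forward(x)
    records = []
    for row, i in enumerate(idx):
        score = float(scores[row])
        pred = POSITIVE if score >= model.config.threshold else NEGATIVE
        true = POSITIVE if dataset.labels[i] > 0.5 else NEGATIVE
        records.append(PredictionRecord(dataset.keys[i], true, score, pred, features[row].copy()))
    return records


def allergen_error_zscores(records: Iterable[PredictionRecord]) -> pd.DataFrame:
    """Per-allergen false-prediction percentage and Z-score across allergens.

    Errors are pooled over whatever folds the records came from (wrong
    predictions summed over total predictions per allergen).  Z-scores use
    the population standard deviation across allergens; an allergen is an
    outlier when |Z| > 3.  If every allergen has the same error rate the
    standard deviation is zero and, by convention, all Z-scores are 0 and
    nothing is flagged.
    """
    records = list(records)
    by_allergen: dict[str, list[PredictionRecord]] = {}
    for r in records:
        by_allergen.setdefault(r.allergen_id, []).append(r)
    if len(by_allergen) < 3:
        raise ValueError("need at least 3 allergens for a Z-score report")
    rows = []
    for allergen in sorted(by_allergen):
        rs = by_allergen[allergen]
        n_false = sum(not r.correct for r in rs)
        rows.append({"allergen_id": allergen, "n": len(rs), "n_false": n_false,
                     "error_pct": 100.0 * n_false / len(rs)})
    df = pd.DataFrame(rows)
    x = df["error_pct"].to_numpy()
    sd = float(x.std())  # population (n-denominator)
    if sd == 0.0:
        df["z"] = 0.0
    else:
        df["z"] = (x - x.mean()) / sd
    df["outlier"] = df["z"].abs() > 3.0
    return df
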