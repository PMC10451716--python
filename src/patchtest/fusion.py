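"""Cross-modality feature redundancy and pairwise feature fusion.

Penultimate-layer feature vectors extracted per chamber from two modality
models are (a) compared with the per-chamber Pearson correlation to gauge
how redundant the two learned representations are, and (b) concatenated and
fed to an RBF-kernel support vector machine (C = 3.5) to test whether the
pair is complementary — whether fusing them classifies better than either
modality alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .classifier import PredictionRecord
from .phantom import NEGATIVE, POSITIVE


@dataclass
class ModalityFeatures:
    """Per-chamber feature vectors of one modality, aligned on chamber keys."""

    modality: str
    keys: list[tuple]
    matrix: np.ndarray  # (n_chambers, feature_width)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.keys):
            raise ValueError("feature matrix must be (n_chambers, width) aligned with keys")

    @classmethod
    def from_records(cls, modality: str, records: Sequence[PredictionRecord]) -> "ModalityFeatures":
        recs = sorted(records, key=lambda r: r.key)
        return cls(modality, [r.key for r in recs], np.stack([r.feature_vector for r in recs]))

    def aligned_with(self, other: "ModalityFeatures") -> tuple[np.ndarray, np.ndarray]:
        if self.keys != other.keys:
            if set(self.keys) != set(other.keys):
                raise ValueError("modalities evaluate different chamber sets")
            order = {k: i for i, k in enumerate(other.keys)}
            idx = np.array([order[k] for k in self.keys])
            return self.matrix, other.matrix[idx]
        return self.matrix, other.matrix


@dataclass(frozen=True)
class CorrelationSummary:
    """Mean and sd of absolute per-chamber Pearson coefficients for a pair."""

    modality_a: str
    modality_b: str
    mean_abs_r: float
    sd_abs_r: float
    n_chambers: int
    n_skipped: int = 0


def pairwise_feature_correlation(a: ModalityFeatures, b: ModalityFeatures) -> CorrelationSummary:
    """Redundancy of two modality representations.

    For every chamber the two feature vectors are treated as paired samples
    and their Pearson coefficient r is computed; the summary is the mean and
    standard deviation of |r| over chambers.  Chambers where either vector
    has zero variance (r undefined) are skipped with a warning.
    """
    ma, mb = a.aligned_with(b)
    if ma.shape[1] != mb.shape[1]:
        raise ValueError("feature vector lengths differ between modalities")
    ca = ma - ma.mean(axis=1, keepdims=True)
    cb = mb - mb.mean(axis=1, keepdims=True)
    na = np.linalg.norm(ca, axis=1)
    nb = np.linalg.norm(cb, axis=1)
    ok = (na > 0) & (nb > 0)
    n_skipped = int((~ok).sum())
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} chambers with zero-variance features", RuntimeWarning, stacklevel=2)
    if not ok.any():
        raise ValueError("no chamber has non-degenerate features")
    r = np.abs((ca[ok] * cb[ok]).sum(axis=1) / (na[ok] * nb[ok]))
    return CorrelationSummary(a.modality, b.modality, float(r.mean()), float(r.std()), int(ok.sum()), n_skipped)


@dataclass
class FusedClassifier:
    """Standardize-then-SVM(RBF) pipeline fitted on concatenated features."""

    pipeline: object
    modalities: tuple[str, str]


def fuse_and_classify(
    a: ModalityFeatures,
    b: ModalityFeatures,
    labels: dict[tuple, str],
    train_keys: Sequence[tuple],
    val_keys: Sequence[tuple],
    c_param: float = 3.5,
    seed: int = 0,
) -> tuple[FusedClassifier, list[PredictionRecord]]:
    """Concatenate two modalities' features and classify with an RBF-SVM.

    Features are standardized (fit on the training chambers only), the SVM
    uses C = 3.5 and the "scale" gamma heuristic, and validation decisions
    are taken from the sign of the decision function.  Deterministic given
    the seed.
    """
    ma, mb = a.aligned_with(b)
    fused = np.concatenate([ma, mb], axis=1)
    index = {k: i for i, k in enumerate(a.keys)}
    tr = np.array([index[k] for k in train_keys])
    va = np.array([index[k] for k in val_keys])
    y_tr = np.array([1.0 if labels[k] == POSITIVE else 0.0 for k in train_keys])
    if len(set(y_tr)) < 2:
        raise ValueError("single-class training side")
    pipe = make_pipeline(
        StandardScaler(),
        SVC(kernel="rbf", C=c_param, gamma="scale", random_state=seed),
    )
    pipe.fit(fused[tr], y_tr)
    scores = pipe.decision_function(fused[va])
    records = []
    for k, s in zip(val_keys, scores):
        pred = POSITIVE if s > 0 else NEGATIVE
        records.append(PredictionRecord(k, labels[k], float(s), pred, fused[index[k]]))
    return FusedClassifier(pipe, (a.modality, b.modality)), records
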