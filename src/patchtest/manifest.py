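"""Annotation-manifest handling: filtering, class bookkeeping, split plans.

A manifest is a :class:`pandas.DataFrame` with one row per annotated chamber
(columns: ``patient_id, area_index, chamber_index, x0, y0, x1, y1,
allergen_id, grade, timepoint``).  All dataset partitioning is *patient
grouped*: every image of a patient falls on exactly one side of every split,
so no patient identity leaks between training and validation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .phantom import GRADES, MANIFEST_COLUMNS, grade_to_binary

SCHEMES = ("holdout_70_30", "kfold_5", "five_by_two")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a chamber manifest CSV, validating schema and grade vocabulary."""
    df = pd.read_csv(path, dtype={"patient_id": str, "allergen_id": str, "grade": str})
    if "bleed_victim" not in df.columns:  # optional phantom metadata
        df["bleed_victim"] = False
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    bad = set(df["grade"]) - {"none", "irritant", *GRADES}
    if bad:
        raise ValueError(f"unknown grades in manifest: {sorted(bad)}")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def filter_dye_allergens(
    manifest: pd.DataFrame, dye_allergen_ids: set[str] | frozenset[str]
) -> tuple[pd.DataFrame, int]:
    """Drop rows whose allergen dyes the skin.

    Skin-staining agents (paraphenylenediamine, textile dye mix) leave
    pigment that the camera reads as hemoglobin, corrupting the redness map;
    the analysis excludes them up front.  Returns the filtered manifest
    (original row order preserved) and the number of rows removed.
    """
    keep = ~manifest["allergen_id"].isin(set(dye_allergen_ids))
    filtered = manifest.loc[keep].reset_index(drop=True)
    return filtered, int((~keep).sum())


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def class_breakdown(manifest: pd.DataFrame) -> pd.DataFrame:
    """Counts and nearest-integer percentages per grade, plus a total row.

    Percentages round half away from zero; e.g. a 722/211/230/27 cohort
    (n = 1190) prints 61/18/19/2.
    """
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    grades = manifest["grade"].replace({"irritant": "none"})
    counts = [int((grades == g).sum()) for g in GRADES]
    total = sum(counts)
    pct = [_round_half_away(100.0 * c / total) for c in counts]
    rows = [{"grade": g, "count": c, "percent": p} for g, c, p in zip(GRADES, counts, pct)]
    rows.append({"grade": "total", "count": total, "percent": 100})
    return pd.DataFrame(rows)


@dataclass
class SplitPlan:
    """Patient-grouped partition for hold-out, 5-fold, or 5x2 CV.

    ``assignments`` maps ``(repetition, role)`` to a sorted list of patient
    ids, where *role* is ``"train"``/``"val"`` for the hold-out scheme,
    ``"fold0"``..``"fold4"`` (validation folds) for 5-fold CV, and
    ``"half0"``/``"half1"`` for the five 50/50 repetitions of 5x2 CV.
    """

    scheme: str
    seed: int
    patients: list[str]
    assignments: dict[tuple[int, str], list[str]] = field(default_factory=dict)

    @property
    def n_repetitions(self) -> int:
        return {"holdout_70_30": 1, "kfold_5": 1, "five_by_two": 5}[self.scheme]

    def train_val(self, repetition: int = 0, fold: int = 0) -> tuple[set[str], set[str]]:
        """Training / validation patient sets for one repetition.

        For ``kfold_5``, ``fold`` selects the held-out fold.  For
        ``five_by_two``, ``fold`` selects which half validates (the other
        trains).
        """
        if self.scheme == "holdout_70_30":
            return set(self.assignments[(0, "train")]), set(self.assignments[(0, "val")])
        if self.scheme == "kfold_5":
            val = set(self.assignments[(0, f"fold{fold}")])
            return set(self.patients) - val, val
        if self.scheme == "five_by_two":
            a = set(self.assignments[(repetition, "half0")])
            b = set(self.assignments[(repetition, "half1")])
            return (b, a) if fold == 0 else (a, b)
        raise ValueError(f"unknown scheme: {self.scheme!r}")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "scheme": self.scheme,
            "seed": self.seed,
            "patients": self.patients,
            "assignments": [
                {"repetition": rep, "role": role, "patients": pats}
                for (rep, role), pats in sorted(self.assignments.items())
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "SplitPlan":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        payload = json.loads(text)
        plan = cls(payload["scheme"], payload["seed"], payload["patients"])
        for entry in payload["assignments"]:
            plan.assignments[(entry["repetition"], entry["role"])] = entry["patients"]
        return plan


def make_split(manifest: pd.DataFrame, scheme: str, seed: int, train_fraction: float = 0.7) -> SplitPlan:
    """Build a patient-grouped :class:`SplitPlan`.

    Splitting operates on the set of distinct patient ids only, so filtering
    rows (e.g. dye allergens) before or after splitting yields the same plan.
    Fractional patients in the hold-out scheme round toward the training side.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme: {scheme!r} (expected one of {SCHEMES})")
    patients = sorted(manifest["patient_id"].astype(str).unique())
    n = len(patients)
    min_needed = {"holdout_70_30": 4, "kfold_5": 5, "five_by_two": 4}[scheme]
    if n < min_needed:
        raise ValueError(f"{scheme} needs at least {min_needed} patients, got {n}")

    plan = SplitPlan(scheme=scheme, seed=seed, patients=patients)
    if scheme == "holdout_70_30":
        rng = np.random.default_rng(seed)
        order = [patients[i] for i in rng.permutation(n)]
        n_train = math.ceil(train_fraction * n)
        if n_train >= n:
            n_train = n - 1
        plan.assignments[(0, "train")] = sorted(order[:n_train])
        plan.assignments[(0, "val")] = sorted(order[n_train:])
    elif scheme == "kfold_5":
        rng = np.random.default_rng(seed)
        order = [patients[i] for i in rng.permutation(n)]
        for k in range(5):
            plan.assignments[(0, f"fold{k}")] = sorted(order[k::5])
    else:  # five_by_two
        for rep in range(5):
            rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
            order = [patients[i] for i in rng.permutation(n)]
            half = n // 2
            plan.assignments[(rep, "half0")] = sorted(order[:half])
            plan.assignments[(rep, "half1")] = sorted(order[half:])
    _check_plan(plan)
    return plan


def _check_plan(plan: SplitPlan) -> None:
    pats = set(plan.patients)
    if plan.scheme == "holdout_70_30":
        tr, va = plan.train_val()
        assert tr.isdisjoint(va) and tr | va == pats
    elif plan.scheme == "kfold_5":
        folds = [set(plan.assignments[(0, f"fold{k}")]) for k in range(5)]
        assert set().union(*folds) == pats
        assert sum(len(f) for f in folds) == len(pats)
    else:
        for rep in range(plan.n_repetitions):
            a = set(plan.assignments[(rep, "half0")])
            b = set(plan.assignments[(rep, "half1")])
            assert a.isdisjoint(b) and a | b == pats


def binary_labels(manifest: pd.DataFrame) -> pd.Series:
    """Per-row binary reading (``negative``/``positive``) of the grade column."""
    return manifest["grade"].map(grade_to_binary)
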