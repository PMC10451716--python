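"""Synthetic multi-modal patch-test phantom.

Epicutaneous patch testing applies allergen-filled chambers to the upper
back; after removal the skin is photographed with a multi-spectral camera
that exports six co-registered "modalities" per capture area: the plain
color image, a false-color hemoglobin map (redness), and four texture-family
maps (texture, fine lines, folds, volumes).  One patch spans two vertically
adjacent capture areas, so the bottom edge of area 1 abuts the top edge of
area 2.

This module renders a cohort of such captures with the statistical
structure the downstream analysis relies on:

* per-chamber reaction grades drawn from a configurable distribution over
  ``none / + / ++ / +++`` (ICDRG-style);
* graded erythema that is visible in the color image and strongest and
  most localized in the redness map;
* textural aberrations (texture / fine lines / folds / volumes) only for
  strong (``++``/``+++``) reactions;
* optional *bleed*: a strong reaction's erythema spreading into one
  adjacent chamber — including across the area-1/area-2 boundary — without
  changing the neighbor's label (the classic false-positive hazard for
  cropped-ROI classification);
* optional skin-dyeing allergens whose dark pigment corrupts the
  hemoglobin map regardless of the true grade.

Everything is deterministic given ``PhantomConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .geometry import Roi

MODALITIES = ("color", "redness", "texture", "fine_lines", "folds", "volumes")

#: Canonical reaction grades, in increasing severity.
GRADES = ("none", "+", "++", "+++")

#: Numeric severity level per accepted grade label.  "irritant" reactions are
#: morphologically distinct but read as negative, like "none".
GRADE_LEVEL = {"none": 0, "irritant": 0, "+": 1, "++": 2, "+++": 3}

NEGATIVE, POSITIVE = "negative", "positive"

#: Default allergen panel; chamber slot ``k`` of a patch receives entry ``k``.
DEFAULT_PANEL = (
    "Nickel sulfate",
    "Fragrance mix I",
    "PPD",
    "Cobalt chloride",
    "MCI/MI",
    "Potassium dichromate",
    "Textile dye mix",
    "Colophonium",
    "Neomycin sulfate",
    "Formaldehyde",
    "Lanolin alcohol",
    "Myroxylon pereirae",
)

MANIFEST_COLUMNS = (
    "patient_id",
    "area_index",
    "chamber_index",
    "x0",
    "y0",
    "x1",
    "y1",
    "allergen_id",
    "grade",
    "timepoint",
    "bleed_victim",
)


def grade_to_binary(grade: str) -> str:
    """Collapse an ICDRG-style grade to the binary reading.

    ``none`` and ``irritant`` read negative; ``+``, ``++`` and ``+++`` read
    positive.  Unknown labels are rejected.
    """
    if grade not in GRADE_LEVEL:
        raise ValueError(f"unknown grade label: {grade!r}")
    return POSITIVE if GRADE_LEVEL[grade] > 0 else NEGATIVE


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the clinical study the phantom emulates: 200 patients,
    480x480 captures, six 110 px chambers per area, and a grade mix of
    61/18/19/2 % for none/+/++/+++.
    """

    n_patients: int = 200
    chambers_per_area: int = 6
    image_size: int = 480
    chamber_size: int = 110
    grade_probabilities: tuple[float, float, float, float] = (0.61, 0.18, 0.19, 0.02)
    bleed_probability: float = 0.15
    dye_allergen_ids: frozenset[str] = frozenset()
    allergen_panel: tuple[str, ...] = DEFAULT_PANEL
    erythema_gain: float = 0.16
    texture_gain: float = 0.22
    noise_sd: float = 0.02
    #: sd of the per-patient baseline hemoglobin shift (vasomotor state);
    #: makes absolute in-ROI redness unreliable across patients, so reading
    #: a reaction requires comparison against the surrounding skin
    patient_offset_sd: float = 0.06
    bleed_gain: float = 1.0
    signal_mode: str = "redness_dominant"  # or "complementary"
    timepoint: int = 72
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chambers_per_area not in (4, 6):
            raise ValueError("chambers_per_area must be 4 or 6 (two-column patch layout)")
        p = np.asarray(self.grade_probabilities, dtype=float)
        if p.shape != (4,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("grade_probabilities must be 4 non-negative values summing to 1")
        if self.image_size < 2 * self.chamber_size:
            raise ValueError("image_size must be at least twice the chamber size")
        n_slots = 2 * self.chambers_per_area
        if len(self.allergen_panel) < n_slots:
            raise ValueError(f"allergen panel must provide >= {n_slots} allergens")
        unknown = set(self.dye_allergen_ids) - set(self.allergen_panel)
        if unknown:
            raise ValueError(f"dye allergens not in panel: {sorted(unknown)}")
        if self.signal_mode not in ("redness_dominant", "complementary"):
            raise ValueError(f"unknown signal_mode: {self.signal_mode!r}")
        # Strict non-overlap of the 2 x R chamber grid.
        rows = self.chambers_per_area // 2
        if self.chamber_size >= self.image_size // 2 or self.chamber_size >= self.image_size // rows:
            raise ValueError("chambers cannot be placed without overlap at this image size")


@dataclass(frozen=True)
class ChamberAnnotation:
    """One allergen chamber: bounding box, identity and clinical grade."""

    patient_id: str
    area_index: int
    chamber_index: int
    bbox: Roi
    allergen_id: str
    grade: str
    timepoint: int = 72
    #: true if a neighboring chamber's reaction bled into this one (the label
    #: is unaffected; metadata for analyzing context-dependent errors)
    bleed_victim: bool = False

    def __post_init__(self) -> None:
        if self.grade not in GRADE_LEVEL:
            raise ValueError(f"unknown grade label: {self.grade!r}")
        if self.bbox.is_degenerate():
            raise ValueError("degenerate bounding box")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.patient_id, self.area_index, self.allergen_id)


@dataclass
class ModalitySet:
    """The six co-registered uint8 RGB images of one capture area."""

    color: np.ndarray
    redness: np.ndarray
    texture: np.ndarray
    fine_lines: np.ndarray
    folds: np.ndarray
    volumes: np.ndarray

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in MODALITIES:
            raise KeyError(f"unknown modality: {name!r}")
        return getattr(self, name)

    def items(self):
        return ((m, getattr(self, m)) for m in MODALITIES)


@dataclass
class PhantomCapture:
    """One capture area of one patient's patch."""

    patient_id: str
    area_index: int
    images: ModalitySet
    annotations: list[ChamberAnnotation]


@dataclass
class Cohort:
    captures: list[PhantomCapture]
    manifest: pd.DataFrame
    config: PhantomConfig

    def capture(self, patient_id: str, area_index: int) -> PhantomCapture:
        for c in self.captures:
            if c.patient_id == patient_id and c.area_index == area_index:
                return c
        raise KeyError((patient_id, area_index))


# ---------------------------------------------------------------------------
# rendering helpers


def _chamber_grid(config: PhantomConfig) -> list[Roi]:
    """Chamber boxes on the combined two-area canvas (height 2*image_size).

    Chambers are laid out as a regular 2-column grid per area, numbered
    row-major within each area; slots 0..C-1 are area 1, C..2C-1 area 2.
    """
    s, c = config.image_size, config.chamber_size
    rows = config.chambers_per_area // 2
    boxes: list[Roi] = []
    for area in (0, 1):
        for r in range(rows):
            yc = area * s + int(round(s * (2 * r + 1) / (2 * rows)))
            for col in (0, 1):
                xc = int(round(s * (2 * col + 1) / 4))
                boxes.append(Roi(xc - c // 2, yc - c // 2, xc - c // 2 + c, yc - c // 2 + c))
    for i, a in enumerate(boxes):
        for b in boxes[i + 1 :]:
            if a.overlaps(b):  # defensive; __post_init__ should have rejected
                raise ValueError("chamber layout overlaps")
    return boxes


def _neighbors(config: PhantomConfig) -> list[list[int]]:
    """Grid adjacency (up/down/left/right) across the combined canvas."""
    rows_total = config.chambers_per_area  # 2 areas x (C/2) rows, 2 cols
    adj: list[list[int]] = []
    for slot in range(2 * config.chambers_per_area):
        r, col = divmod(slot, 2)
        out = []
        if col == 1:
            out.append(slot - 1)
        if col == 0:
            out.append(slot + 1)
        if r > 0:
            out.append(slot - 2)
        if r < rows_total - 1:
            out.append(slot + 2)
        adj.append(out)
    return adj


def _blob(shape: tuple[int, int], center: tuple[float, float], sigma: float) -> np.ndarray:
    """Gaussian bump on a (H, W) canvas, evaluated on a +-3.5 sigma window."""
    h, w = shape
    cy, cx = center
    out = np.zeros(shape, dtype=np.float64)
    r = int(np.ceil(3.5 * sigma))
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return out
    yy = np.arange(y0, y1, dtype=np.float64)[:, None] - cy
    xx = np.arange(x0, x1, dtype=np.float64)[None, :] - cx
    out[y0:y1, x0:x1] = np.exp(-(yy**2 + xx**2) / (2.0 * sigma**2))
    return out


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], scale: float) -> np.ndarray:
    """Low-frequency skin mottle: bilinear upsampling of coarse noise."""
    coarse = rng.normal(0.0, 1.0, size=(10, 6))
    ys = np.linspace(0, coarse.shape[0] - 1, shape[0])
    xs = np.linspace(0, coarse.shape[1] - 1, shape[1])
    yi, xi = np.floor(ys).astype(int), np.floor(xs).astype(int)
    yi = np.clip(yi, 0, coarse.shape[0] - 2)
    xi = np.clip(xi, 0, coarse.shape[1] - 2)
    fy, fx = ys - yi, xs - xi
    top = coarse[yi][:, xi] * (1 - fx) + coarse[yi][:, xi + 1] * fx
    bot = coarse[yi + 1][:, xi] * (1 - fx) + coarse[yi + 1][:, xi + 1] * fx
    return scale * (top * (1 - fy[:, None]) + bot * fy[:, None])


def _ramp(field: np.ndarray, lo: Sequence[float], hi: Sequence[float]) -> np.ndarray:
    """Linear two-anchor false-color map of a [0, 1] scalar field -> float RGB."""
    f = np.clip(field, 0.0, 1.0)[..., None]
    return np.asarray(lo) * (1.0 - f) + np.asarray(hi) * f


def _quantize(rgb: np.ndarray, rng: np.random.Generator, noise_sd: float) -> np.ndarray:
    noisy = rgb + rng.normal(0.0, noise_sd, size=rgb.shape)
    return (np.clip(noisy, 0.0, 1.0) * 255.0).round().astype(np.uint8)


def _render_patient(config: PhantomConfig, patient_index: int) -> tuple[PhantomCapture, PhantomCapture]:
    s = config.image_size
    canvas = (2 * s, s)
    patient_id = f"P{patient_index:03d}"
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, patient_index]))

    boxes = _chamber_grid(config)
    adj = _neighbors(config)
    n_slots = 2 * config.chambers_per_area
    panel = config.allergen_panel[:n_slots]

    grades = [GRADES[g] for g in rng.choice(4, size=n_slots, p=config.grade_probabilities)]
    levels = np.array([GRADE_LEVEL[g] for g in grades], dtype=float)

    # Per-chamber signal partition between visible erythema (color image) and
    # hemoglobin (redness map).  In the default mode hemoglobin carries the
    # full signal while the visible expression varies per chamber (weak
    # reactions can be spectrally evident yet barely visible), so the redness
    # map is the more reliable single modality; in complementary mode each
    # positive chamber expresses predominantly in one of the two, so neither
    # map alone suffices and fusing their features recovers the full signal.
    if config.signal_mode == "complementary":
        dominant = rng.random(n_slots) < 0.5
        w_vis = np.where(dominant, 0.9, 0.15)
        w_hemo = np.where(dominant, 0.15, 0.9)
    else:
        w_vis = rng.uniform(0.25, 1.0, size=n_slots)
        w_hemo = np.full(n_slots, 1.0)

    hemo = np.zeros(canvas)
    vis = np.zeros(canvas)
    rough = np.zeros(canvas)
    depth = np.zeros(canvas)  # fine lines / folds share this at two scales
    vol = np.zeros(canvas)
    pigment = np.zeros(canvas)

    c = config.chamber_size
    centers = [((b.y0 + b.y1) / 2.0, (b.x0 + b.x1) / 2.0) for b in boxes]

    for slot in range(n_slots):
        lvl = levels[slot]
        ctr = centers[slot]
        if lvl > 0:
            # severity jitter keeps grades overlapping slightly, like real skin
            sev = lvl * (1.0 + rng.normal(0.0, 0.08))
            vis += config.erythema_gain * sev * w_vis[slot] * _blob(canvas, ctr, 0.55 * c)
            hemo += 1.4 * config.erythema_gain * sev * w_hemo[slot] * _blob(canvas, ctr, 0.40 * c)
        if lvl >= 2:
            amp = config.texture_gain * (lvl - 1.0)
            bump = _blob(canvas, ctr, 0.40 * c)
            phase = rng.uniform(0, 2 * np.pi, size=4)
            yy = np.arange(canvas[0])[:, None]
            xx = np.arange(canvas[1])[None, :]
            ripple = 0.5 + 0.5 * np.sin(2 * np.pi * yy / 9.0 + phase[0]) * np.sin(2 * np.pi * xx / 9.0 + phase[1])
            rough += amp * bump * ripple
            depth += 0.8 * amp * bump * (0.5 + 0.5 * np.sin(2 * np.pi * (yy + xx) / 14.0 + phase[2]))
            vol += 0.9 * amp * bump * (0.35 + 0.65 * np.sin(2 * np.pi * yy / 22.0 + phase[3]) ** 2)
        if panel[slot] in config.dye_allergen_ids:
            # dye deposit: dark pigment read by the camera as hemoglobin
            pigment += 0.55 * _blob(canvas, ctr, 0.33 * c)
            hemo += 0.9 * _blob(canvas, ctr, 0.33 * c)

    # bleed: a strong reaction spreads contiguously into one adjacent chamber,
    # depositing reaction-like erythema there plus a connecting track through
    # the inter-chamber gap (the spread is one continuous patch of skin, so
    # the corridor between the chambers reddens too)
    bled_into = np.zeros(n_slots, dtype=bool)
    for slot in range(n_slots):
        if levels[slot] >= 2 and rng.random() < config.bleed_probability:
            victim = int(rng.choice(adj[slot]))
            bled_into[victim] = True
            amp = config.bleed_gain * (1.0 + rng.normal(0.0, 0.08))
            vis += config.erythema_gain * amp * w_vis[slot] * _blob(canvas, centers[victim], 0.55 * c)
            hemo += 1.4 * config.erythema_gain * amp * w_hemo[slot] * _blob(canvas, centers[victim], 0.40 * c)
            mid = (
                0.5 * (centers[slot][0] + centers[victim][0]),
                0.5 * (centers[slot][1] + centers[victim][1]),
            )
            vis += config.erythema_gain * amp * w_vis[slot] * _blob(canvas, mid, 0.16 * c)
            hemo += 1.4 * config.erythema_gain * amp * w_hemo[slot] * _blob(canvas, mid, 0.12 * c)

    # --- false-color rendering ------------------------------------------------
    base = np.array([0.72, 0.55, 0.47]) + rng.normal(0.0, 0.015, size=3)
    mottle = _smooth_field(rng, canvas, 0.03)

    color = np.empty((*canvas, 3))
    color[..., 0] = base[0] + mottle + 0.85 * vis
    color[..., 1] = base[1] + mottle - 0.30 * vis
    color[..., 2] = base[2] + mottle - 0.30 * vis
    color -= pigment[..., None] * np.array([0.50, 0.55, 0.60])

    offset = rng.normal(0.0, config.patient_offset_sd)
    h = np.clip(0.12 + offset + 0.5 * mottle + hemo, 0.0, 1.0)
    redness = _ramp(h, lo=(0.16, 0.10, 0.30), hi=(0.95, 0.30, 0.18))

    texture = _ramp(np.clip(0.10 + rough + 0.3 * mottle, 0, 1), lo=(0.15, 0.18, 0.25), hi=(0.95, 0.65, 0.20))
    fine = _ramp(np.clip(0.12 + depth + 0.3 * mottle, 0, 1), lo=(0.96, 0.96, 0.94), hi=(0.45, 0.02, 0.02))
    folds = _ramp(np.clip(0.10 + 0.7 * depth + 0.4 * mottle, 0, 1), lo=(0.96, 0.96, 0.94), hi=(0.50, 0.05, 0.05))
    volumes = _ramp(np.clip(0.5 + vol + 0.3 * mottle, 0, 1), lo=(0.45, 0.02, 0.02), hi=(0.30, 0.05, 0.45))

    planes = {
        "color": color,
        "redness": redness,
        "texture": texture,
        "fine_lines": fine,
        "folds": folds,
        "volumes": volumes,
    }
    quantized = {m: _quantize(img, rng, config.noise_sd) for m, img in planes.items()}

    captures = []
    for area in (1, 2):
        sl = slice(0, s) if area == 1 else slice(s, 2 * s)
        images = ModalitySet(**{m: quantized[m][sl].copy() for m in MODALITIES})
        annots = []
        for slot in range(n_slots):
            if (slot < config.chambers_per_area) != (area == 1):
                continue
            b = boxes[slot]
            local = b.shifted(dy=-s) if area == 2 else b
            annots.append(
                ChamberAnnotation(
                    patient_id=patient_id,
                    area_index=area,
                    chamber_index=slot % config.chambers_per_area,
                    bbox=local,
                    allergen_id=panel[slot],
                    grade=grades[slot],
                    timepoint=config.timepoint,
                    bleed_victim=bool(bled_into[slot]),
                )
            )
        captures.append(PhantomCapture(patient_id, area, images, annots))
    return captures[0], captures[1]


def iter_cohort(config: PhantomConfig) -> Iterator[PhantomCapture]:
    """Yield captures patient by patient (two areas per patient)."""
    for i in range(config.n_patients):
        a1, a2 = _render_patient(config, i)
        yield a1
        yield a2


def generate_cohort(config: PhantomConfig) -> Cohort:
    """Materialize the full synthetic cohort in memory.

    Returns the captures together with a manifest of one row per chamber
    (patient, area, bounding box, allergen, grade, timepoint).
    """
    captures = list(iter_cohort(config))
    rows = []
    for cap in captures:
        for a in cap.annotations:
            rows.append(
                (
                    a.patient_id,
                    a.area_index,
                    a.chamber_index,
                    a.bbox.x0,
                    a.bbox.y0,
                    a.bbox.x1,
                    a.bbox.y1,
                    a.allergen_id,
                    a.grade,
                    a.timepoint,
                    a.bleed_victim,
                )
            )
    manifest = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    return Cohort(captures, manifest, config)


def write_cohort(cohort: Cohort, outdir: str | Path, image_format: str = "png") -> Path:
    """Write a cohort to ``patient_<id>/area_<k>/<modality>.<ext>`` plus
    ``manifest.csv`` and a JSON echo of the configuration.

    PNG is lossless (exact round-trip); "jpeg" writes quality-95 JPEG like
    the camera software's export; "both" writes the pair.
    """
    if image_format not in ("png", "jpeg", "both"):
        raise ValueError(f"unknown image format: {image_format!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for cap in cohort.captures:
        d = outdir / f"patient_{cap.patient_id}" / f"area_{cap.area_index}"
        d.mkdir(parents=True, exist_ok=True)
        for modality, img in cap.images.items():
            pil = Image.fromarray(img)
            if image_format in ("png", "both"):
                pil.save(d / f"{modality}.png")
            if image_format in ("jpeg", "both"):
                pil.save(d / f"{modality}.jpg", quality=95)
    cohort.manifest.to_csv(outdir / "manifest.csv", index=False)
    cfg = dataclasses.asdict(cohort.config)
    cfg["dye_allergen_ids"] = sorted(cfg["dye_allergen_ids"])
    cfg["allergen_panel"] = list(cfg["allergen_panel"])
    cfg["grade_probabilities"] = list(cfg["grade_probabilities"])
    (outdir / "config.json").write_text(json.dumps(cfg, indent=2))
    return outdir


def load_cohort(directory: str | Path) -> Cohort:
    """Read a cohort previously written by :func:`write_cohort` (PNG preferred)."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    config = PhantomConfig(**{
        **json.loads((directory / "config.json").read_text()),
        "dye_allergen_ids": frozenset(json.loads((directory / "config.json").read_text())["dye_allergen_ids"]),
    })
    config = dataclasses.replace(
        config,
        allergen_panel=tuple(config.allergen_panel),
        grade_probabilities=tuple(config.grade_probabilities),
    )
    captures: dict[tuple[str, int], PhantomCapture] = {}
    for (pid, area), group in manifest.groupby(["patient_id", "area_index"], sort=False):
        d = directory / f"patient_{pid}" / f"area_{area}"
        imgs = {}
        for m in MODALITIES:
            path = d / f"{m}.png"
            if not path.exists():
                path = d / f"{m}.jpg"
            imgs[m] = np.asarray(Image.open(path).convert("RGB"))
        annots = [
            ChamberAnnotation(
                patient_id=str(r.patient_id),
                area_index=int(r.area_index),
                chamber_index=int(r.chamber_index),
                bbox=Roi(int(r.x0), int(r.y0), int(r.x1), int(r.y1)),
                allergen_id=str(r.allergen_id),
                grade=str(r.grade),
                timepoint=int(r.timepoint),
                bleed_victim=bool(getattr(r, "bleed_victim", False)),
            )
            for r in group.itertuples()
        ]
        captures[(str(pid), int(area))] = PhantomCapture(str(pid), int(area), ModalitySet(**imgs), annots)
    return Cohort(list(captures.values()), manifest, config)
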