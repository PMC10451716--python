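"""Chamber-level image pre-processing: Crop, Alpha Mask, and CEAM.

Classifying the reaction to a single allergen requires isolating its chamber
region of interest (ROI).  Three schemes are implemented:

* **crop** — keep only the ROI pixels (the conventional approach; discards
  all context, so erythema bleeding in from a neighboring chamber is
  indistinguishable from a true reaction);
* **am** (alpha mask) — keep the whole image but multiply it element-wise
  with a mask ``M`` that is 1 inside the ROI and ``background_alpha``
  (default 0.5) everywhere else: ``I' = I ⊙ M``.  The ROI is highlighted
  while the surrounding context stays visible at half brightness;
* **ceam** (contextually enhanced alpha mask) — alpha masking plus a strip
  of ``context_rows`` (default 75) pixel rows taken from the adjacent
  capture area along the shared physical edge, restoring the context that
  is lost because one patch spans two separately captured areas.

The model transform mirrors a standard fine-tuning stack: seeded random
horizontal/vertical flips and rotation within +-20 degrees at train time,
bilinear resize to 224x224, and per-channel ImageNet normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize, rotate

from .geometry import Roi

SCHEMES = ("crop", "am", "ceam")

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float64)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float64)


@dataclass
class AlphaMask:
    """Grayscale mask with value 1 inside ``roi``, ``background_alpha`` outside."""

    values: np.ndarray
    roi: Roi

    @classmethod
    def for_image(cls, shape: tuple[int, int], roi: Roi, background_alpha: float = 0.5) -> "AlphaMask":
        if not 0.0 <= background_alpha <= 1.0:
            raise ValueError("background_alpha must be in [0, 1]")
        h, w = shape
        if not roi.within(h, w) or roi.is_degenerate():
            raise ValueError(f"roi {roi} not within {h}x{w} image")
        m = np.full((h, w), background_alpha, dtype=np.float64)
        m[roi.y0 : roi.y1, roi.x0 : roi.x1] = 1.0
        return cls(values=m, roi=roi)


@dataclass
class PreprocessedSample:
    """A scheme-processed chamber image, ready for the model transform."""

    image: np.ndarray  # uint8 RGB
    scheme: str
    roi: Roi  # ROI in the (possibly shifted) output coordinates
    source_id: tuple | None = None


def _check_roi(image: np.ndarray, roi: Roi) -> None:
    h, w = image.shape[:2]
    if roi.is_degenerate():
        raise ValueError(f"degenerate roi: {roi}")
    if not roi.within(h, w):
        raise ValueError(f"roi {roi} outside {h}x{w} image")


def crop_roi(image: np.ndarray, roi: Roi, source_id: tuple | None = None) -> PreprocessedSample:
    """Exact pixel sub-rectangle of the ROI; no resampling."""
    _check_roi(image, roi)
    out = image[roi.y0 : roi.y1, roi.x0 : roi.x1].copy()
    return PreprocessedSample(out, "crop", Roi(0, 0, roi.width, roi.height), source_id)


def apply_alpha_mask(
    image: np.ndarray,
    roi: Roi,
    background_alpha: float = 0.5,
    source_id: tuple | None = None,
) -> PreprocessedSample:
    """Element-wise product ``I' = I ⊙ M`` with the ROI alpha mask.

    ROI pixels are bit-identical to the input; background pixels are scaled
    by ``background_alpha`` across all channels (rounded to the nearest
    integer for integer images).
    """
    _check_roi(image, roi)
    mask = AlphaMask.for_image(image.shape[:2], roi, background_alpha)
    product = image.astype(np.float64) * mask.values[..., None]
    if np.issubdtype(image.dtype, np.integer):
        out = np.rint(product).astype(image.dtype)
    else:
        out = product.astype(image.dtype)
    return PreprocessedSample(out, "am", roi, source_id)


def apply_ceam(
    image: np.ndarray,
    roi: Roi,
    adjacent_image: np.ndarray,
    area_index: int,
    context_rows: int = 75,
    background_alpha: float = 0.5,
    source_id: tuple | None = None,
) -> PreprocessedSample:
    """Alpha mask over a composite extended with the adjacent area's edge rows.

    Area 1 sits physically above area 2, so the shared edge is the bottom of
    area 1 / the top of area 2.  For an area-1 image the top ``context_rows``
    rows of area 2 are appended below; for an area-2 image the bottom
    ``context_rows`` rows of area 1 are prepended above, shifting the ROI's
    vertical coordinates by ``+context_rows``.  The context strip is part of
    the background and is dimmed at ``background_alpha``.

    ``context_rows=0`` reduces to :func:`apply_alpha_mask`.
    """
    _check_roi(image, roi)
    if area_index not in (1, 2):
        raise ValueError("area_index must be 1 or 2")
    if adjacent_image.shape[1] != image.shape[1]:
        raise ValueError("image and adjacent image widths differ")
    if context_rows < 0 or context_rows >= adjacent_image.shape[0]:
        raise ValueError("context_rows must be in [0, adjacent image height)")

    if context_rows == 0:
        out = apply_alpha_mask(image, roi, background_alpha, source_id)
        out.scheme = "ceam"
        return out

    if area_index == 1:
        strip = adjacent_image[:context_rows]
        composite = np.concatenate([image, strip], axis=0)
        shifted = roi
    else:
        strip = adjacent_image[-context_rows:]
        composite = np.concatenate([strip, image], axis=0)
        shifted = roi.shifted(dy=context_rows)

    out = apply_alpha_mask(composite, shifted, background_alpha, source_id)
    out.scheme = "ceam"
    return out


def preprocess(
    scheme: str,
    image: np.ndarray,
    roi: Roi,
    adjacent_image: np.ndarray | None = None,
    area_index: int | None = None,
    context_rows: int = 75,
    background_alpha: float = 0.5,
    source_id: tuple | None = None,
) -> PreprocessedSample:
    """Dispatch on the pre-processing scheme name."""
    if scheme == "crop":
        return crop_roi(image, roi, source_id)
    if scheme == "am":
        return apply_alpha_mask(image, roi, background_alpha, source_id)
    if scheme == "ceam":
        if adjacent_image is None or area_index is None:
            raise ValueError("ceam requires adjacent_image and area_index")
        return apply_ceam(image, roi, adjacent_image, area_index, context_rows, background_alpha, source_id)
    raise ValueError(f"unknown scheme: {scheme!r}")


def model_transform(
    sample: PreprocessedSample | np.ndarray,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
    out_size: int = 224,
    max_rotation_deg: float = 20.0,
) -> np.ndarray:
    """Augment (train mode), resize and normalize a sample for the model.

    Train mode applies random horizontal and vertical flips (p = 0.5 each)
    and a rotation drawn uniformly from [-20, +20] degrees with black fill,
    driven by the supplied generator so runs are reproducible.  All samples
    are then resized to ``out_size x out_size`` with bilinear interpolation
    and normalized per channel with the ImageNet mean and standard
    deviation.  Returns a float32 array of shape ``(3, out_size, out_size)``.
    """
    image = sample.image if isinstance(sample, PreprocessedSample) else sample
    img = image.astype(np.float64) / 255.0 if np.issubdtype(image.dtype, np.integer) else image.astype(np.float64)

    if train_mode:
        if rng is None:
            raise ValueError("train-mode transform requires an rng")
        if rng.random() < 0.5:
            img = img[:, ::-1]
        if rng.random() < 0.5:
            img = img[::-1, :]
        angle = rng.uniform(-max_rotation_deg, max_rotation_deg)
        img = rotate(img, angle, resize=False, order=1, mode="constant", cval=0.0, preserve_range=True)

    img = resize(img, (out_size, out_size), order=1, mode="edge", anti_aliasing=False, preserve_range=True)
    img = (img - IMAGENET_MEAN) / IMAGENET_STD
    return np.ascontiguousarray(img.transpose(2, 0, 1).astype(np.float32))
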