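"""Image containers, color conversions, component labeling and evaluation metrics.

Images are plain numpy arrays throughout the package:

* RGB image  -- ``(H, W, 3) uint8``
* gray image -- ``(H, W) uint8`` (ITU-R BT.601 luma)
* HSV image  -- ``(H, W, 3) float64``, every channel in ``[0, 1]``
  (hue is the angle divided by 360 degrees)
* binary mask -- ``(H, W) bool``

Validation helpers raise :class:`~woundkit.errors.InvalidInputError` rather
than silently coercing, because a shape mismatch at this level usually means
two pipeline stages were fed images from different sources.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import color as skcolor

from .errors import InvalidInputError, UndefinedMetricError

__all__ = [
    "as_rgb",
    "as_gray",
    "as_mask",
    "rgb_to_gray",
    "rgb_to_hsv",
    "connected_components",
    "LabeledRegions",
    "SegmentationMetrics",
    "coverage_metrics",
    "ClassificationCounts",
    "classification_metrics",
]

_MIN_SIDE = 3


def as_rgb(img) -> np.ndarray:
    """Validate and return an RGB image as ``(H, W, 3) uint8``."""
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InvalidInputError(f"expected (H, W, 3) RGB array, got shape {arr.shape}")
    if arr.shape[0] < _MIN_SIDE or arr.shape[1] < _MIN_SIDE:
        raise InvalidInputError("image must be at least 3x3 pixels")
    if arr.dtype != np.uint8:
        if arr.min() < 0 or arr.max() > 255:
            raise InvalidInputError("RGB channel values must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def as_gray(img) -> np.ndarray:
    """Validate and return a gray image as ``(H, W) uint8``."""
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise InvalidInputError(f"expected (H, W) gray array, got shape {arr.shape}")
    if arr.size == 0:
        raise InvalidInputError("empty image")
    if arr.dtype != np.uint8:
        if arr.min() < 0 or arr.max() > 255:
            raise InvalidInputError("gray values must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def as_mask(mask) -> np.ndarray:
    """Validate and return a binary mask as ``(H, W) bool``."""
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise InvalidInputError(f"expected (H, W) mask, got shape {arr.shape}")
    if arr.dtype != bool:
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise InvalidInputError("mask values must be 0/1")
        arr = arr.astype(bool)
    return arr


def rgb_to_gray(img) -> np.ndarray:
    """Convert RGB to gray with the BT.601 luma weights.

    ``Y = 0.299 R + 0.587 G + 0.114 B`` rounded half-up to the nearest
    integer, so a pure ``(v, v, v)`` gray triple maps back to ``v`` exactly.
    """
    arr = as_rgb(img).astype(np.float64)
    y = 0.299 * arr[..., 0] + 0.587 * arr[..., 1] + 0.114 * arr[..., 2]
    return np.floor(y + 0.5).astype(np.uint8)  # round half-up


def rgb_to_hsv(img) -> np.ndarray:
    """Convert RGB to HSV with all channels normalized to ``[0, 1]``.

    Hue is the standard hexcone angle divided by 360 degrees.  For black
    pixels (and any pixel with zero saturation) hue is defined as 0 so the
    output never contains NaN.
    """
    arr = as_rgb(img)
    hsv = skcolor.rgb2hsv(arr)
    return np.nan_to_num(hsv, nan=0.0)


@dataclass(frozen=True)
class LabeledRegions:
    """Connected-component labeling result.

    ``label_map`` holds 0 for background and labels ``1..n_regions``
    assigned in order of the first pixel encountered in a row-major scan.
    ``sizes[i]`` is the pixel count of label ``i + 1``.
    """

    label_map: np.ndarray
    n_regions: int
    sizes: np.ndarray

    def pixels(self, label: int) -> np.ndarray:
        """Return the ``(n, 2)`` array of (row, col) coordinates of a region."""
        return np.argwhere(self.label_map == label)


def connected_components(mask, connectivity: int = 8) -> LabeledRegions:
    """Label maximal connected foreground sets of a binary mask.

    Parameters
    ----------
    mask : array-like of bool
        Foreground is nonzero.
    connectivity : {4, 8}
        Pixel adjacency; 8 also joins diagonal neighbors.
    """
    arr = as_mask(mask)
    if connectivity not in (4, 8):
        raise InvalidInputError("connectivity must be 4 or 8")
    structure = ndi.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    raw, n = ndi.label(arr, structure=structure)
    # scipy labels in row-major first-encounter order already, but relabel
    # defensively so the ordering contract does not depend on its internals.
    order = _first_encounter_order(raw, n)
    label_map = order[raw]
    sizes = np.bincount(label_map.ravel(), minlength=n + 1)[1:]
    return LabeledRegions(label_map=label_map, n_regions=int(n), sizes=sizes)


def _first_encounter_order(raw: np.ndarray, n: int) -> np.ndarray:
    if n == 0:
        return np.zeros(1, dtype=np.int32)
    flat = raw.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    idx = np.flatnonzero(flat)
    np.minimum.at(first, flat[idx], idx)
    order = np.zeros(n + 1, dtype=np.int32)
    order[1 + np.argsort(first[1:], kind="stable")] = np.arange(1, n + 1)
    return order


@dataclass(frozen=True)
class SegmentationMetrics:
    """Boundary-based segmentation agreement against a manual mask.

    ``coverage_rate = (N1 - CN) / N1`` and ``exceed_rate = CP / N1`` where
    N1 is the manual foreground size, CN the manual pixels the automatic
    mask missed and CP the automatic pixels outside the manual mask.
    """

    coverage_rate: float
    exceed_rate: float


def coverage_metrics(auto_mask, manual_mask) -> SegmentationMetrics:
    auto = as_mask(auto_mask)
    manual = as_mask(manual_mask)
    if auto.shape != manual.shape:
        raise InvalidInputError("masks must share a shape")
    n1 = int(manual.sum())
    if n1 == 0:
        raise UndefinedMetricError("manual mask has no foreground pixels")
    cn = int((manual & ~auto).sum())
    cp = int((auto & ~manual).sum())
    return SegmentationMetrics(coverage_rate=(n1 - cn) / n1, exceed_rate=cp / n1)


@dataclass(frozen=True)
class ClassificationCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def classification_metrics(counts: ClassificationCounts) -> dict:
    """Accuracy, sensitivity (TPR), specificity (SPC) and precision (PPV).

    Ratios with a zero denominator are reported as ``math.nan`` so a
    degenerate confusion table never raises mid-report.
    """
    if counts.total == 0:
        raise InvalidInputError("all counts are zero")

    def ratio(num, den):
        return num / den if den > 0 else math.nan

    return {
        "accuracy": (counts.tp + counts.tn) / counts.total,
        "tpr": ratio(counts.tp, counts.tp + counts.fn),
        "spc": ratio(counts.tn, counts.tn + counts.fp),
        "ppv": ratio(counts.tp, counts.tp + counts.fp),
    }
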