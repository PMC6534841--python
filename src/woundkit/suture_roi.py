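"""Suture-site positioning: cross features, clustering and ROI detection.

Suture stitches run perpendicular to the incision, so each stitch leaves a
plus-shaped mark.  Otsu binarization highlights the wound, a morphological
opening with a 5x5 cross structuring element keeps only cross-shaped pixel
groups, and each connected group collapses to one feature point.  The points
are clustered agglomeratively; the number of suture sites is the corner of a
decaying cluster-score curve, located with Rosin's unimodal-threshold
(maximum chord distance) rule.  Each cluster's padded bounding rectangle is
one region of interest.

Three score-curve variants are available (see :func:`score_curve`):

``"formula"``
    The piecewise score ``S = 1 - a/b`` / ``0`` / ``b/a - 1`` with
    ``a = n/k`` (mean elements per cluster) and ``b = k``, and
    ``iVar = 1/S`` where positive.  This score depends on ``n`` and ``k``
    only, so it is kept for reference but cannot react to the point layout.
``"silhouette"``
    ``iVar = 1/S`` with the standard mean silhouette coefficient.
``"dispersion"``
    ``Var(k)`` = mean within-cluster squared deviation, reported on a log
    scale and anchored at ``k = 1`` (total variance).  Its decay is steep
    while genuine sites are still merged and flattens once every site has
    its own cluster, so the Rosin corner lands on the true site count.
    This is the default used by the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.cluster import hierarchy as sch
from skimage import filters as skfilters
from sklearn.metrics import silhouette_score

from .errors import InvalidInputError, NoFeaturePointsError
from .imaging_core import as_gray, as_mask, connected_components

__all__ = [
    "cross_kernel",
    "binarize_otsu",
    "binarize_dark_marks",
    "cross_feature_pixels",
    "extract_feature_points",
    "ClusterHierarchy",
    "build_hierarchy",
    "ClusterScoreCurve",
    "score_piecewise",
    "score_curve",
    "rosin_threshold",
    "select_cluster_count",
    "ROI",
    "detect_rois",
]


def cross_kernel() -> np.ndarray:
    """The 5x5 cross-shaped structuring element (ones on center row/column)."""
    k = np.zeros((5, 5), dtype=np.uint8)
    k[2, :] = 1
    k[:, 2] = 1
    return k


def binarize_otsu(gray) -> np.ndarray:
    """Otsu threshold (maximal between-class variance); pixels > t are True.

    A constant image has no between-class split; the result is an all-zero
    mask and a warning.
    """
    img = as_gray(gray)
    if np.unique(img).size < 2:
        warnings.warn("constant image: Otsu threshold undefined, returning empty mask")
        return np.zeros(img.shape, dtype=bool)
    t = skfilters.threshold_otsu(img)
    return img > t


def binarize_dark_marks(
    gray, mask=None, max_splits: int = 3, dark_fraction: float = 0.25
) -> np.ndarray:
    """Isolate dark suture marks by iterated Otsu splitting.

    Suture threads are the darkest structures in the wound area, but the
    masked wound image can hold three gray populations (skin margin, wound
    bed, sutures); a single Otsu split then leaves the whole wound bed in
    the dark class.  The dark class is therefore re-split with Otsu while it
    still covers more than ``dark_fraction`` of the analysis mask (at most
    ``max_splits`` times), after which it contains only the marks.
    """
    img = as_gray(gray)
    region = np.ones(img.shape, dtype=bool) if mask is None else as_mask(mask)
    dark = region.copy()
    for _ in range(max_splits):
        vals = img[dark]
        if vals.size == 0 or np.unique(vals).size < 2:
            break
        t = skfilters.threshold_otsu(vals)
        new_dark = dark & (img <= t)
        if not new_dark.any():
            break
        dark = new_dark
        if dark.sum() <= dark_fraction * region.sum():
            break
    return dark


def cross_feature_pixels(binary, kernel: np.ndarray | None = None) -> np.ndarray:
    """Morphological opening (erosion then dilation) with the cross kernel."""
    mask = as_mask(binary)
    kernel = cross_kernel() if kernel is None else np.asarray(kernel, dtype=bool)
    eroded = ndi.binary_erosion(mask, structure=kernel)
    return ndi.binary_dilation(eroded, structure=kernel)


def extract_feature_points(cross_mask) -> np.ndarray:
    """One (row, col) point per connected component: its rounded centroid.

    Rounding is half-up.  Returns an ``(n, 2)`` int array (possibly empty).
    """
    mask = as_mask(cross_mask)
    ccl = connected_components(mask, connectivity=8)
    points = []
    for label in range(1, ccl.n_regions + 1):
        pix = ccl.pixels(label)
        centroid = pix.mean(axis=0)
        points.append(np.floor(centroid + 0.5).astype(int))
    return np.array(points, dtype=int).reshape(-1, 2)


@dataclass(frozen=True)
class ClusterHierarchy:
    """Agglomerative dendrogram over feature points."""

    points: np.ndarray
    linkage_matrix: np.ndarray
    linkage: str

    @property
    def n_points(self) -> int:
        return len(self.points)

    def cut(self, k: int) -> np.ndarray:
        """Labels (1..k) of the k-cluster partition."""
        if k < 1 or k > self.n_points:
            raise InvalidInputError(f"k must lie in [1, {self.n_points}]")
        if k == 1:
            return np.ones(self.n_points, dtype=int)
        return sch.fcluster(self.linkage_matrix, t=k, criterion="maxclust")


def build_hierarchy(points, linkage: str = "average") -> ClusterHierarchy:
    """Cluster feature points agglomeratively with Euclidean distances."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 2:
        raise NoFeaturePointsError("need at least 2 feature points to cluster")
    if linkage not in ("single", "complete", "average", "ward"):
        raise InvalidInputError(f"unsupported linkage {linkage!r}")
    z = sch.linkage(pts, method=linkage)
    return ClusterHierarchy(points=pts, linkage_matrix=z, linkage=linkage)


@dataclass(frozen=True)
class ClusterScoreCurve:
    """Score values indexed by candidate cluster count ``k`` (ascending)."""

    ks: np.ndarray
    values: np.ndarray
    variant: str

    def __post_init__(self):
        if len(self.ks) != len(self.values):
            raise InvalidInputError("ks and values must have equal length")


def score_piecewise(a: float, b: float) -> float:
    """Piecewise cluster score: 1-a/b if a<b; 0 if a=b; b/a-1 if a>b."""
    if a < b:
        return 1.0 - a / b
    if a == b:
        return 0.0
    return b / a - 1.0


def score_curve(h: ClusterHierarchy, variant: str = "dispersion") -> ClusterScoreCurve:
    """Score each candidate cluster count of a hierarchy (see module docs)."""
    n = h.n_points
    if variant == "formula":
        if n < 4:
            raise NoFeaturePointsError("formula curve needs >= 4 points")
        ks, vals = [], []
        for k in range(2, n // 2 + 1):
            s = score_piecewise(n / k, float(k))
            if s > 0:
                ks.append(k)
                vals.append(1.0 / s)
        if not ks:
            raise NoFeaturePointsError("no positive scores: curve undefined")
        return ClusterScoreCurve(np.array(ks), np.array(vals), variant)

    if variant == "silhouette":
        if n < 4:
            raise NoFeaturePointsError("silhouette curve needs >= 4 points")
        ks, vals = [], []
        for k in range(2, n // 2 + 1):
            labels = h.cut(k)
            if np.unique(labels).size < 2:
                continue
            s = float(silhouette_score(h.points, labels))
            if s > 0:
                ks.append(k)
                vals.append(1.0 / s)
        if not ks:
            raise NoFeaturePointsError("no positive silhouette scores")
        return ClusterScoreCurve(np.array(ks), np.array(vals), variant)

    if variant == "dispersion":
        if n < 4:
            raise NoFeaturePointsError("dispersion curve needs >= 4 points")
        ks, vals = [], []
        for k in range(1, max(n // 2, 2) + 1):
            labels = h.cut(k)
            w = 0.0
            for lab in np.unique(labels):
                sub = h.points[labels == lab]
                w += float(((sub - sub.mean(axis=0)) ** 2).sum())
            ks.append(k)
            vals.append(np.log(max(w / n, 1e-9)))
        return ClusterScoreCurve(np.array(ks), np.array(vals), variant)

    raise InvalidInputError(f"unknown score variant {variant!r}")


def rosin_threshold(curve: ClusterScoreCurve, kmin: int | None = None) -> int:
    """Corner of a decaying curve by Rosin's maximum-chord-distance rule.

    The chord runs from the maximum-value point to the last point; the
    selected ``k`` maximizes the perpendicular distance to that chord (ties
    break to the smaller ``k``).  A numerically straight curve returns the
    first eligible ``k``.  ``kmin`` restricts the answer (used to exclude
    the ``k = 1`` anchor of dispersion curves).

    The argmax is invariant to positive rescaling of either axis, so the
    choice does not depend on the units of the score.
    """
    ks = np.asarray(curve.ks, dtype=float)
    vals = np.asarray(curve.values, dtype=float)
    if len(ks) == 0:
        raise InvalidInputError("empty curve")
    eligible = np.ones(len(ks), dtype=bool) if kmin is None else ks >= kmin
    if not eligible.any():
        raise InvalidInputError("no eligible k on the curve")
    if len(ks) < 3:
        return int(ks[eligible][0])

    i0 = int(np.argmax(vals))
    x0, y0 = ks[i0], vals[i0]
    x1, y1 = ks[-1], vals[-1]
    dx, dy = x1 - x0, y1 - y0
    norm = float(np.hypot(dx, dy))
    if norm == 0:
        return int(ks[eligible][0])
    dist = np.abs(dx * (vals - y0) - dy * (ks - x0)) / norm
    dist[: i0 + 1] = -1.0  # the corner lies strictly after the peak
    dist[~eligible] = -1.0
    if dist.max() <= 1e-12:
        return int(ks[eligible][0])
    return int(ks[int(np.argmax(dist))])


def select_cluster_count(h: ClusterHierarchy, variant: str = "dispersion") -> int:
    """Number of suture sites: Rosin corner of the score curve, k >= 2."""
    n = h.n_points
    if n < 4:
        return min(2, n)
    curve = score_curve(h, variant=variant)
    return rosin_threshold(curve, kmin=2)


@dataclass(frozen=True)
class ROI:
    """Axis-aligned bounding rectangle over one feature-point cluster."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int
    points: np.ndarray

    def __post_init__(self):
        if self.x_min > self.x_max or self.y_min > self.y_max:
            raise InvalidInputError("degenerate ROI bounds")

    @property
    def width(self) -> int:
        return self.x_max - self.x_min + 1

    @property
    def height(self) -> int:
        return self.y_max - self.y_min + 1

    def to_dict(self) -> dict:
        return {
            "x_min": self.x_min,
            "y_min": self.y_min,
            "x_max": self.x_max,
            "y_max": self.y_max,
            "n_points": len(self.points),
        }


def detect_rois(
    h: ClusterHierarchy,
    k: int,
    pad: int = 10,
    image_shape: tuple[int, int] | None = None,
) -> list[ROI]:
    """Cut the hierarchy at ``k`` clusters and box each cluster.

    Boxes use (x, y) = (col, row) convention, are expanded by ``pad`` pixels
    on every side and clipped to ``image_shape`` when given.  Always returns
    exactly ``k`` ROIs, ordered by cluster label.
    """
    if not 2 <= k <= h.n_points:
        raise InvalidInputError("k must lie in [2, n_points]")
    labels = h.cut(k)
    rois = []
    for lab in np.unique(labels):
        member = h.points[labels == lab]
        y_min, x_min = member.min(axis=0)
        y_max, x_max = member.max(axis=0)
        x0, y0 = int(x_min) - pad, int(y_min) - pad
        x1, y1 = int(x_max) + pad, int(y_max) + pad
        if image_shape is not None:
            hgt, wid = image_shape
            x0, y0 = max(x0, 0), max(y0, 0)
            x1, y1 = min(x1, wid - 1), min(y1, hgt - 1)
        rois.append(ROI(x_min=x0, y_min=y0, x_max=x1, y_max=y1, points=member))
    return rois
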