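"""Skin-area demarcation from enforced edge maps.

The enforced edges partition the photograph into candidate regions: each
connected edge set (GE) induces the region it encloses (RG).  Regions whose
mean HSV color falls outside the skin ranges are discarded (RG'); the
surviving region with the most individually skin-colored pixels provides the
per-image optimum skin color, and every remaining region is kept or dropped
by how far its mean color sits from that optimum.  The union of kept regions
is the possible-skin mask.

Because open contours have no well-defined interior, a region is realized as
the hole-filled morphological closing of its edge set (disk radius
``close_radius``).  Where regions nest (a wound contour inside a skin
contour), interior pixels belong to the innermost enclosing set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk

from .errors import EmptySkinError, InvalidInputError
from .imaging_core import LabeledRegions, as_mask, connected_components

__all__ = [
    "SkinRange",
    "PresenceParams",
    "RegionCollection",
    "SkinColorStats",
    "OptimumSkinColor",
    "delimit_regions",
    "region_stats",
    "filter_skin_regions",
    "optimum_skin_color",
    "assign_presence",
]


@dataclass(frozen=True)
class SkinRange:
    """Inclusive HSV bounds for skin color (all channels in [0, 1])."""

    h: tuple[float, float] = (0.035, 0.7)
    s: tuple[float, float] = (0.005, 0.8)
    v: tuple[float, float] = (0.35, 0.9)

    def __post_init__(self):
        for lo, hi in (self.h, self.s, self.v):
            if not lo < hi:
                raise InvalidInputError("each channel range needs lower < upper")

    def contains_stats(self, stats: "SkinColorStats") -> bool:
        return (
            self.h[0] <= stats.sh <= self.h[1]
            and self.s[0] <= stats.ss <= self.s[1]
            and self.v[0] <= stats.sv <= self.v[1]
        )

    def pixel_mask(self, hsv: np.ndarray) -> np.ndarray:
        """Boolean mask of pixels individually inside the skin ranges."""
        h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
        return (
            (h >= self.h[0]) & (h <= self.h[1])
            & (s >= self.s[0]) & (s <= self.s[1])
            & (v >= self.v[0]) & (v <= self.v[1])
        )


@dataclass(frozen=True)
class PresenceParams:
    """Per-channel distance-to-optimum thresholds for the presence rule."""

    phi: float = 0.25   # hue
    vphi: float = 0.25  # saturation
    chi: float = 0.2    # value

    def __post_init__(self):
        for v in (self.phi, self.vphi, self.chi):
            if not 0 < v < 1:
                raise InvalidInputError("presence thresholds must lie in (0, 1)")


@dataclass(frozen=True)
class SkinColorStats:
    """Mean H, S, V over one region's pixels."""

    sh: float
    ss: float
    sv: float


@dataclass(frozen=True)
class OptimumSkinColor:
    """Mean H, S, V of the reference (most-skin-colored) region."""

    sh_optm: float
    ss_optm: float
    sv_optm: float


@dataclass
class RegionCollection:
    """Edge sets and the image regions they induce.

    ``edge_labels`` labels the edge pixels (the GE groups); ``regions`` maps
    each pixel to the label of its innermost enclosing edge set (RG / RG').
    ``labels`` lists the labels still present (filtering drops entries from
    the list but keeps the label numbering stable).
    """

    source_edges: np.ndarray
    edge_labels: LabeledRegions
    region_map: np.ndarray
    labels: list[int] = field(default_factory=list)
    whole_image_fallback: bool = False

    def region_pixels(self, label: int) -> np.ndarray:
        return np.argwhere(self.region_map == label)


def delimit_regions(edges, close_radius: int = 5) -> RegionCollection:
    """Group edges into sets and realize each set's enclosed region.

    An empty edge map yields a single region covering the whole image with
    ``whole_image_fallback`` set, so downstream color filtering still runs.
    """
    edge_arr = as_mask(edges)
    ge = connected_components(edge_arr, connectivity=8)
    h, w = edge_arr.shape
    region_map = np.zeros((h, w), dtype=np.int32)

    if ge.n_regions == 0:
        region_map[:] = 1
        fallback = LabeledRegions(
            label_map=np.ones((h, w), dtype=np.int32),
            n_regions=1,
            sizes=np.array([h * w]),
        )
        return RegionCollection(
            source_edges=edge_arr,
            edge_labels=fallback,
            region_map=region_map,
            labels=[1],
            whole_image_fallback=True,
        )

    footprint = disk(close_radius)
    filled = []
    for label in range(1, ge.n_regions + 1):
        pix = ge.pixels(label)
        rmin, cmin = pix.min(axis=0)
        rmax, cmax = pix.max(axis=0)
        # work in a window padded beyond the image so the closing's erosion
        # never clips a contour that runs near the image border
        pad = 2 * close_radius + 2
        r0, c0 = rmin - pad, cmin - pad
        sub = np.zeros((rmax - rmin + 1 + 2 * pad, cmax - cmin + 1 + 2 * pad), dtype=bool)
        sub[pix[:, 0] - r0, pix[:, 1] - c0] = True
        closed = ndi.binary_closing(sub, structure=footprint)
        region = ndi.binary_fill_holes(closed) | sub  # a region always contains its edges
        # crop back to the image
        rr0, cc0 = max(r0, 0), max(c0, 0)
        rr1 = min(r0 + region.shape[0], h)
        cc1 = min(c0 + region.shape[1], w)
        region = region[rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0]
        filled.append((label, (rr0, cc0), region))

    # paint larger regions first so nested (smaller) regions overwrite them:
    # interior pixels end up with their innermost enclosing edge set.
    filled.sort(key=lambda item: -int(item[2].sum()))
    for label, (r0, c0), region in filled:
        view = region_map[r0 : r0 + region.shape[0], c0 : c0 + region.shape[1]]
        view[region] = label

    labels = sorted(int(v) for v in np.unique(region_map) if v != 0)
    return RegionCollection(
        source_edges=edge_arr,
        edge_labels=ge,
        region_map=region_map,
        labels=labels,
    )


def region_stats(hsv, pixels: np.ndarray) -> SkinColorStats:
    """Channel means of an HSV image over a set of (row, col) coordinates."""
    if len(pixels) == 0:
        raise InvalidInputError("empty region")
    vals = np.asarray(hsv)[pixels[:, 0], pixels[:, 1]]
    sh, ss, sv = vals.mean(axis=0)
    return SkinColorStats(sh=float(sh), ss=float(ss), sv=float(sv))


def filter_skin_regions(
    rg: RegionCollection, hsv, skin_range: SkinRange | None = None
) -> RegionCollection:
    """Drop regions whose mean HSV lies outside the skin ranges (RG -> RG')."""
    skin_range = skin_range or SkinRange()
    kept = []
    for label in rg.labels:
        stats = region_stats(hsv, rg.region_pixels(label))
        if skin_range.contains_stats(stats):
            kept.append(label)
    if not kept:
        raise EmptySkinError("every region was filtered out by the skin color ranges")
    return RegionCollection(
        source_edges=rg.source_edges,
        edge_labels=rg.edge_labels,
        region_map=rg.region_map,
        labels=kept,
        whole_image_fallback=rg.whole_image_fallback,
    )


def optimum_skin_color(
    rgp: RegionCollection, hsv, skin_range: SkinRange | None = None
) -> OptimumSkinColor:
    """Channel means of the region with the most skin-colored pixels.

    The reference region maximizes the count of pixels individually inside
    the skin ranges; ties break to the smaller label.
    """
    if not rgp.labels:
        raise EmptySkinError("RG' is empty")
    skin_range = skin_range or SkinRange()
    in_range = skin_range.pixel_mask(np.asarray(hsv))
    best_label, best_count = None, -1
    for label in rgp.labels:
        count = int(in_range[rgp.region_map == label].sum())
        if count > best_count:
            best_label, best_count = label, count
    stats = region_stats(hsv, rgp.region_pixels(best_label))
    return OptimumSkinColor(sh_optm=stats.sh, ss_optm=stats.ss, sv_optm=stats.sv)


def assign_presence(
    rgp: RegionCollection,
    optm: OptimumSkinColor,
    hsv,
    params: PresenceParams | None = None,
) -> np.ndarray:
    """Union mask of regions whose mean color is near the optimum skin color.

    A region is present (skin) when all three absolute channel differences
    from the optimum fall below the thresholds.  Pixels in no region are
    background.
    """
    params = params or PresenceParams()
    mask = np.zeros(rgp.region_map.shape, dtype=bool)
    for label in rgp.labels:
        stats = region_stats(hsv, rgp.region_pixels(label))
        dsh = abs(optm.sh_optm - stats.sh)
        dss = abs(optm.ss_optm - stats.ss)
        dsv = abs(optm.sv_optm - stats.sv)
        if dsh < params.phi and dss < params.vphi and dsv < params.chi:
            mask |= rgp.region_map == label
    return mask
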