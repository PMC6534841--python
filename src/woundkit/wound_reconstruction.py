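"""Wound-area reconstruction from the optimized edge sets (AE).

The wound's edges at the optimized threshold are an incomplete outline.  The
reconstruction fills their envelope, thins it to a topological skeleton,
extracts the dominant straight segments with a probabilistic Hough
transform, chains the segment endpoints into a closed polygon, and dilates
the filled polygon until it contains every AE edge pixel — the coverage
area.  A complementary calculation then intersects the margin-dilated
coverage area with the demarcated skin support so the final wound image
keeps the wound plus the clinically relevant surrounding skin while all
background pixels are zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import draw as skdraw
from skimage import morphology as skmorph
from skimage.morphology import disk
from skimage import transform as sktransform

from .errors import EmptyWoundError
from .imaging_core import as_mask, as_rgb

__all__ = [
    "HoughParams",
    "BackboneShape",
    "WoundResult",
    "skeletonize_and_lines",
    "connect_endpoints",
    "complement_wound",
]


@dataclass(frozen=True)
class HoughParams:
    threshold: int = 10
    line_length: int = 10
    line_gap: int = 5
    seed: int = 0  # the probabilistic transform samples pixels; fixed for determinism


@dataclass
class BackboneShape:
    """Skeleton, Hough lines and (after endpoint connection) coverage area."""

    edges: np.ndarray
    skeleton: np.ndarray
    hough_lines: list[tuple[tuple[int, int], tuple[int, int]]]
    envelope: np.ndarray | None = None
    closed_boundary: list[tuple[int, int]] = field(default_factory=list)
    coverage_area: np.ndarray | None = None


def skeletonize_and_lines(
    ae, close_radius: int = 5, hough: HoughParams | None = None
) -> BackboneShape:
    """Skeletonize the filled AE envelope and extract dominant line segments."""
    edges = as_mask(ae)
    if not edges.any():
        raise EmptyWoundError("no optimized edges to reconstruct from")
    hough = hough or HoughParams()
    envelope = ndi.binary_fill_holes(ndi.binary_closing(edges, structure=disk(close_radius)))
    skeleton = skmorph.skeletonize(envelope)
    lines = sktransform.probabilistic_hough_line(
        skeleton,
        threshold=hough.threshold,
        line_length=hough.line_length,
        line_gap=hough.line_gap,
        rng=np.random.default_rng(hough.seed),
    )
    # skimage returns ((x0, y0), (x1, y1)); keep that convention
    lines = [tuple(map(tuple, line)) for line in lines]
    lines.sort()
    return BackboneShape(edges=edges, skeleton=skeleton, hough_lines=lines, envelope=envelope)


def connect_endpoints(bb: BackboneShape) -> BackboneShape:
    """Chain line endpoints into a closed polygon and grow the coverage area.

    Endpoints are joined greedily: starting from the lexicographically first
    endpoint, always hop to the nearest unused one, then close the loop.
    The filled polygon, united with the filled AE envelope so the boundary
    geometry stays tight, is dilated by exactly the radius needed for it to
    contain every AE edge pixel (usually zero).  With fewer than two
    endpoints the convex hull of AE substitutes for the polygon.
    """
    shape = bb.edges.shape
    endpoints: list[tuple[int, int]] = []
    for (x0, y0), (x1, y1) in bb.hough_lines:
        endpoints.append((x0, y0))
        endpoints.append((x1, y1))

    if len(endpoints) < 2:
        base = skmorph.convex_hull_image(bb.edges)
        boundary: list[tuple[int, int]] = []
    else:
        boundary = _greedy_chain(endpoints)
        rows = [y for x, y in boundary]
        cols = [x for x, y in boundary]
        rr, cc = skdraw.polygon(rows, cols, shape=shape)
        base = np.zeros(shape, dtype=bool)
        base[rr, cc] = True
        h, w = shape
        closed = boundary + boundary[:1]
        for (x0, y0), (x1, y1) in zip(closed[:-1], closed[1:]):
            lr, lc = skdraw.line(
                int(np.clip(y0, 0, h - 1)), int(np.clip(x0, 0, w - 1)),
                int(np.clip(y1, 0, h - 1)), int(np.clip(x1, 0, w - 1)),
            )
            base[lr, lc] = True

    bb.closed_boundary = boundary
    if bb.envelope is not None:
        base = base | bb.envelope
    bb.coverage_area = _dilate_to_contain(base, bb.edges)
    return bb


def _greedy_chain(endpoints: list[tuple[int, int]]) -> list[tuple[int, int]]:
    remaining = sorted(set(endpoints))
    chain = [remaining.pop(0)]
    while remaining:
        cx, cy = chain[-1]
        j = min(
            range(len(remaining)),
            key=lambda i: ((remaining[i][0] - cx) ** 2 + (remaining[i][1] - cy) ** 2, remaining[i]),
        )
        chain.append(remaining.pop(j))
    return chain


def _dilate_to_contain(base: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Dilate ``base`` by the smallest disk radius that covers ``targets``."""
    if not base.any():
        base = targets.copy()
    missing = targets & ~base
    if not missing.any():
        return base
    dist = ndi.distance_transform_edt(~base)
    radius = int(np.ceil(dist[missing].max()))
    return dist <= radius


@dataclass
class WoundResult:
    """Final wound mask, the masked image, and run provenance."""

    wound_mask: np.ndarray
    wound_image: np.ndarray
    provenance: dict = field(default_factory=dict)


def complement_wound(
    original,
    skin_support,
    bb: BackboneShape,
    margin: int = 15,
    provenance: dict | None = None,
) -> WoundResult:
    """Complementary calculation: coverage area vs. demarcated skin support.

    ``skin_support`` is the filled possible-skin area (skin regions with
    interior holes such as the wound filled in); the wound mask is the
    coverage area dilated by ``margin`` pixels, clipped to that support.
    Pixels outside the mask are zeroed in the output image.
    """
    img = as_rgb(original)
    support = as_mask(skin_support)
    if bb.coverage_area is None:
        raise EmptyWoundError("coverage area missing: run connect_endpoints first")
    grown = ndi.binary_dilation(bb.coverage_area, structure=disk(margin)) if margin > 0 else bb.coverage_area
    wound_mask = grown & support
    if not wound_mask.any():
        raise EmptyWoundError("coverage area does not intersect the skin support")
    wound_image = np.where(wound_mask[..., None], img, 0).astype(np.uint8)
    return WoundResult(
        wound_mask=wound_mask,
        wound_image=wound_image,
        provenance=dict(provenance or {}, margin=margin),
    )
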