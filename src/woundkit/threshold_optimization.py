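"""Self-adaptive Canny threshold search robust to skin-wrinkle clutter.

Wrinkled skin floods an edge map with short, faint, near-parallel contours
that break region delimitation.  The search has two phases:

* **candidate (upward) search** -- raise the high threshold step by step as
  long as the contours that each raise removes look like wrinkles (more than
  ``epsilon`` chord lines of similar slope in spatial proximity), bounded
  above by ``phi_upper * 255``.
* **optimized (downward) search** -- from the candidate value, lower the
  threshold as long as the newly appearing contours are skin-colored (their
  mean RGB within per-channel distances of the mean RGB outside the current
  contours), ignoring wrinkle-like contour groups; bounded below by
  ``phi_lower * 255``.

The searched value is the Canny high threshold; the low threshold follows as
``low_ratio`` times the high one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .edge_enforcement import EnforceParams, detect_edges, enforce_edges, find_endpoints
from .errors import ParameterError
from .imaging_core import as_gray, as_mask, as_rgb, connected_components

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateParams",
    "OptimizedParams",
    "SlopeLine",
    "slope_line_sets",
    "edge_contours",
    "candidate_threshold",
    "optimized_threshold",
    "LOW_RATIO",
]

LOW_RATIO = 0.4  # low Canny threshold as a fraction of the high one


@dataclass(frozen=True)
class CandidateParams:
    """Upward-search tuning: wrinkle-count limit and upper bound."""

    epsilon: int = 20
    phi_upper: float = 0.26
    step: float = 5.0
    slope_tol: float = 10.0   # degrees
    proximity: float = 50.0   # pixels between chord midpoints

    def __post_init__(self):
        if self.epsilon < 1:
            raise ParameterError("epsilon must be >= 1")
        if not 0 < self.phi_upper <= 1:
            raise ParameterError("phi_upper must lie in (0, 1]")


@dataclass(frozen=True)
class OptimizedParams:
    """Downward-search tuning: RGB closeness thresholds and lower bound."""

    epsilon: int = 40
    phi_rgb: float = 38.0    # red channel closeness (0-255 scale)
    vphi_rgb: float = 40.0   # green
    chi_rgb: float = 40.0    # blue
    phi_lower: float = 0.06
    step: float = 5.0
    slope_tol: float = 10.0
    proximity: float = 50.0

    def __post_init__(self):
        if not 0 < self.phi_lower < 1:
            raise ParameterError("phi_lower must lie in (0, 1)")


@dataclass(frozen=True)
class SlopeLine:
    """Chord joining the two extreme points of one open contour."""

    endpoint_a: tuple[int, int]
    endpoint_b: tuple[int, int]
    slope_deg: float  # orientation in [0, 180)
    midpoint: tuple[float, float]


def slope_line_sets(
    edges, slope_tol: float = 10.0, proximity: float = 50.0
) -> list[list[SlopeLine]]:
    """Derive one chord line per open contour and group similar lines.

    Each connected contour with open endpoints contributes the line through
    its two endpoints (falling back to its two farthest pixels when the
    endpoint count is not exactly two); closed contours contribute nothing.
    Lines are grouped by the transitive closure of "slopes within
    ``slope_tol`` degrees and midpoints within ``proximity`` pixels".
    """
    arr = as_mask(edges)
    lines = _contour_chords(arr)
    return _group_lines(lines, slope_tol, proximity)


def _contour_chords(arr: np.ndarray) -> list[SlopeLine]:
    ccl = connected_components(arr, connectivity=8)
    lines: list[SlopeLine] = []
    for label in range(1, ccl.n_regions + 1):
        pix = ccl.pixels(label)
        if len(pix) < 2:
            continue
        sub = np.zeros(arr.shape, dtype=bool)
        sub[pix[:, 0], pix[:, 1]] = True
        eps = [p for p, _ in find_endpoints(sub)]
        if len(eps) == 0:
            continue  # closed contour
        if len(eps) == 2:
            a, b = eps
        else:
            a, b = _farthest_pair(pix)
        dy, dx = b[0] - a[0], b[1] - a[1]
        slope = float(np.degrees(np.arctan2(dy, dx))) % 180.0
        mid = ((a[0] + b[0]) / 2.0, (a[1] + b[1]) / 2.0)
        lines.append(SlopeLine(tuple(a), tuple(b), slope, mid))
    return lines


def _farthest_pair(pix: np.ndarray) -> tuple[tuple[int, int], tuple[int, int]]:
    # exact on the convex hull would be fine; contours are small, brute force
    # over axis extremes is enough and deterministic
    cand = np.unique(
        np.concatenate(
            [
                pix[[pix[:, 0].argmin(), pix[:, 0].argmax(), pix[:, 1].argmin(), pix[:, 1].argmax()]],
            ]
        ),
        axis=0,
    )
    best, best_d = (tuple(pix[0]), tuple(pix[-1])), -1.0
    for i in range(len(cand)):
        d = ((pix - cand[i]) ** 2).sum(axis=1)
        j = int(d.argmax())
        if d[j] > best_d:
            best_d = float(d[j])
            best = (tuple(int(v) for v in cand[i]), tuple(int(v) for v in pix[j]))
    return best


def _slope_close(a: float, b: float, tol: float) -> bool:
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d) <= tol


def _group_lines(
    lines: list[SlopeLine], slope_tol: float, proximity: float
) -> list[list[SlopeLine]]:
    n = len(lines)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _slope_close(lines[i].slope_deg, lines[j].slope_deg, slope_tol):
                mi, mj = lines[i].midpoint, lines[j].midpoint
                if np.hypot(mi[0] - mj[0], mi[1] - mj[1]) <= proximity:
                    parent[find(i)] = find(j)
    groups: dict[int, list[SlopeLine]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(lines[i])
    return list(groups.values())


def edge_contours(gray, high_thr: float, enforce: EnforceParams | None = None) -> tuple[np.ndarray, list[np.ndarray]]:
    """Detect + enforce edges at a threshold and return CC-linked contours.

    Returns the enforced edge map and a list of (n, 2) pixel-coordinate
    arrays, one per contour.
    """
    img = as_gray(gray)
    edges = detect_edges(img, LOW_RATIO * high_thr, high_thr)
    edges = enforce_edges(edges, img, enforce)
    ccl = connected_components(edges, connectivity=8)
    contours = [ccl.pixels(label) for label in range(1, ccl.n_regions + 1)]
    return edges, contours


def _match_contours(
    ga: list[np.ndarray], gb: list[np.ndarray], shape
) -> tuple[list[int], list[np.ndarray]]:
    """Indices and pixels of ``ga`` contours with <50% overlap in ``gb``."""
    gb_mask = np.zeros(shape, dtype=bool)
    for pix in gb:
        gb_mask[pix[:, 0], pix[:, 1]] = True
    idx, unmatched = [], []
    for i, pix in enumerate(ga):
        overlap = gb_mask[pix[:, 0], pix[:, 1]].mean() if len(pix) else 0.0
        if overlap < 0.5:
            idx.append(i)
            unmatched.append(pix)
    return idx, unmatched


def _contour_group_sizes(
    contours: list[np.ndarray], shape, slope_tol: float, proximity: float
) -> list[int]:
    """Per-contour size of its similar-slope line group (0 for closed ones).

    The chord line of every open contour is grouped with the chords of all
    the other contours in the set; a contour embedded in a large group of
    near-parallel neighbors is wrinkle-like.
    """
    lines, owner = [], []
    for i, pix in enumerate(contours):
        if len(pix) < 2:
            owner.append(None)
            continue
        # unlike slope_line_sets, closed contours also get a chord here: a
        # wrinkle's Canny trace is a thin closed loop around the dark line,
        # and its farthest-pair chord is exactly the wrinkle's long axis
        a, b = _farthest_pair(pix)
        dy, dx = b[0] - a[0], b[1] - a[1]
        if dy == 0 and dx == 0:
            owner.append(None)
            continue
        slope = float(np.degrees(np.arctan2(dy, dx))) % 180.0
        mid = ((a[0] + b[0]) / 2.0, (a[1] + b[1]) / 2.0)
        owner.append(len(lines))
        lines.append(SlopeLine(a, b, slope, mid))
    groups = _group_lines(lines, slope_tol, proximity)
    line_group_size = {}
    for g in groups:
        for line in g:
            line_group_size[id(line)] = len(g)
    sizes = []
    for own in owner:
        sizes.append(line_group_size[id(lines[own])] if own is not None else 0)
    return sizes


def candidate_threshold(
    gray,
    init_thr: float = 20.0,
    params: CandidateParams | None = None,
    enforce: EnforceParams | None = None,
) -> float:
    """Upward threshold search (the candidate value).

    Starting at ``init_thr``, raise the threshold while the contours that the
    raise removes form a wrinkle-like group, capped at ``phi_upper * 255``.
    """
    params = params or CandidateParams()
    img = as_gray(gray)
    upper = params.phi_upper * 255.0
    if init_thr >= upper:
        raise ParameterError("init_thr must be below phi_upper * 255")
    thr = float(init_thr)
    _, ga = edge_contours(img, thr, enforce)
    while thr + params.step <= upper:
        _, gb = edge_contours(img, thr + params.step, enforce)
        gc_idx, gc = _match_contours(ga, gb, img.shape)
        # a removed contour is wrinkle-like when it belongs to a large
        # similar-slope group within the full current edge set
        sizes = _contour_group_sizes(ga, img.shape, params.slope_tol, params.proximity)
        wrinkly = any(sizes[i] > params.epsilon for i in gc_idx)
        logger.debug("candidate search: thr=%.1f |GA|=%d |GC|=%d wrinkly=%s", thr, len(ga), len(gc), wrinkly)
        if not wrinkly:
            break
        thr += params.step
        ga = gb
    return thr


def optimized_threshold(
    gray,
    rgb,
    cand_thr: float,
    params: OptimizedParams | None = None,
    enforce: EnforceParams | None = None,
    mask=None,
) -> float:
    """Downward threshold search (the optimized value).

    From the candidate threshold, keep lowering while the newly appearing
    contours are too close in mean RGB to the average color outside the
    current contours (i.e. they add only more skin-like edges), ignoring
    wrinkle-like groups; capped below at ``phi_lower * 255``.

    ``mask`` restricts the outside-color average to the demarcated skin
    area; without it, non-skin background pixels would drag that average
    away from the skin color and stop the search too early.
    """
    params = params or OptimizedParams()
    img = as_gray(gray)
    rgb_arr = as_rgb(rgb).astype(np.float64)
    area = np.ones(img.shape, dtype=bool) if mask is None else as_mask(mask)
    lower = params.phi_lower * 255.0
    if cand_thr < lower:
        raise ParameterError("cand_thr must be at least phi_lower * 255")
    thr = float(cand_thr)
    _, ga = edge_contours(img, thr, enforce)
    while thr - params.step >= lower:
        edges_b, gb = edge_contours(img, thr - params.step, enforce)
        gc_idx, gc = _match_contours(gb, ga, img.shape)
        if not gc:
            break  # lowering changed nothing: the threshold is already settled
        sizes = _contour_group_sizes(gb, img.shape, params.slope_tol, params.proximity)
        informative = [pix for i, pix in zip(gc_idx, gc) if sizes[i] <= params.epsilon]
        if not informative:
            # only wrinkle-like contours appeared; they are ignored and the
            # search keeps lowering past them
            thr -= params.step
            ga = gb
            continue
        new_mean = _mean_rgb(rgb_arr, informative)
        outside_mean = _mean_rgb_outside(rgb_arr, edges_b, area)
        close = (
            abs(new_mean[0] - outside_mean[0]) < params.phi_rgb
            and abs(new_mean[1] - outside_mean[1]) < params.vphi_rgb
            and abs(new_mean[2] - outside_mean[2]) < params.chi_rgb
        )
        logger.debug(
            "optimized search: thr=%.1f |GC'|=%d new=%s outside=%s close=%s",
            thr, len(gc), np.round(new_mean, 1), np.round(outside_mean, 1), close,
        )
        if not close:
            break  # distinctly colored (wound) edges appeared: stop
        thr -= params.step
        ga = gb
    return thr


def _mean_rgb(rgb: np.ndarray, contours: list[np.ndarray]) -> np.ndarray:
    pix = np.concatenate(contours, axis=0)
    return rgb[pix[:, 0], pix[:, 1]].mean(axis=0)


def _mean_rgb_outside(rgb: np.ndarray, edges: np.ndarray, area: np.ndarray) -> np.ndarray:
    outside = ~edges & area
    if not outside.any():
        return rgb.reshape(-1, 3).mean(axis=0)
    return rgb[outside].mean(axis=0)
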