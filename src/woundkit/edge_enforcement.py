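"""Canny edge detection and endpoint-driven edge mending.

Canny output on wound photographs is fragmented: the contour of the wound is
broken wherever local contrast dips below the hysteresis thresholds.  The
mending procedure walks every open edge endpoint and extends it one pixel at
a time toward the neighbor that best continues a genuine intensity boundary.
Candidate neighbors are scored by how strongly they split the endpoint's
3x3 neighborhood into two regions of different mean gray level; a chain
stops when no candidate produces a difference above ``stop_threshold``
(the neighborhood has become flat, i.e. the edge truly ends), when it
reconnects to existing edge pixels (the gap is mended), or at a safety cap.

The result is always a superset of the input edge map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import feature as skfeature

from .errors import ParameterError
from .imaging_core import as_gray, as_mask

__all__ = [
    "EnforceParams",
    "detect_edges",
    "find_endpoints",
    "candidate_extensions",
    "select_extension_point",
    "enforce_edges",
]

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass(frozen=True)
class EnforceParams:
    """Tuning for edge mending.

    stop_threshold : minimal mean gray-level difference (0-255 scale) between
        the two split neighborhood regions for an extension to be accepted.
    max_steps : per-endpoint cap on chain length; guarantees termination.
    """

    stop_threshold: float = 10.0
    max_steps: int = 50

    def __post_init__(self):
        if self.stop_threshold <= 0:
            raise ParameterError("stop_threshold must be positive")
        if self.max_steps < 1:
            raise ParameterError("max_steps must be >= 1")


def detect_edges(gray, low_thr: float, high_thr: float, sigma: float = 1.4) -> np.ndarray:
    """Canny edge detection with thresholds on the 0-255 gray scale.

    Returns a boolean edge map of the input shape.  Deterministic; raising
    ``high_thr`` (with ``low_thr`` scaled along) never adds edge pixels.
    """
    img = as_gray(gray)
    if not 0 <= low_thr < high_thr:
        raise ParameterError(f"need 0 <= low_thr < high_thr, got {low_thr}, {high_thr}")
    return skfeature.canny(
        img.astype(np.float64) / 255.0,
        sigma=sigma,
        low_threshold=low_thr / 255.0,
        high_threshold=high_thr / 255.0,
    )


def find_endpoints(edges) -> list[tuple[tuple[int, int], str]]:
    """Locate open edge endpoints and type them by local connectivity.

    An edge pixel is an endpoint when it has one edge neighbor in its 3x3
    window ("one-connected") or two edge neighbors that are 4-adjacent to
    each other ("two-connected", the thick tip of a diagonal chain).  The
    4-adjacency requirement distinguishes a genuine tip from the corner of
    a right-angle contour, whose two neighbors touch only diagonally.
    Returned in row-major order.
    """
    arr = as_mask(edges)
    kernel = np.ones((3, 3), dtype=np.int32)
    kernel[1, 1] = 0
    ncount = ndi.convolve(arr.astype(np.int32), kernel, mode="constant")
    out: list[tuple[tuple[int, int], str]] = []
    h, w = arr.shape
    for r, c in np.argwhere(arr & ((ncount == 1) | (ncount == 2))):
        nbrs = [
            (r + dr, c + dc)
            for dr, dc in _NEIGHBORS
            if 0 <= r + dr < h and 0 <= c + dc < w and arr[r + dr, c + dc]
        ]
        if len(nbrs) == 1:
            out.append(((int(r), int(c)), "one-connected"))
        elif len(nbrs) == 2:
            (r1, c1), (r2, c2) = nbrs
            if abs(r1 - r2) + abs(c1 - c2) == 1:  # neighbors 4-adjacent: a chain tip
                out.append(((int(r), int(c)), "two-connected"))
    return out


def candidate_extensions(edges, point: tuple[int, int]) -> list[tuple[tuple[int, int], list, list]]:
    """Enumerate extension candidates for an endpoint.

    A background neighbor of ``point`` is a candidate when activating it
    splits the remaining background of the 3x3 window into exactly two
    (4-connected) parts.  Returns ``(candidate, part_a, part_b)`` tuples in
    row-major candidate order; the parts are lists of absolute (row, col)
    background coordinates.
    """
    arr = as_mask(edges)
    h, w = arr.shape
    r0, c0 = point
    window = [
        (r0 + dr, c0 + dc)
        for dr in (-1, 0, 1)
        for dc in (-1, 0, 1)
        if 0 <= r0 + dr < h and 0 <= c0 + dc < w
    ]
    background = [p for p in window if not arr[p]]
    out = []
    for cand in background:
        if max(abs(cand[0] - r0), abs(cand[1] - c0)) != 1:
            continue  # only pixels adjacent to the endpoint extend the edge
        rest = [p for p in background if p != cand]
        parts = _four_connected_parts(rest)
        if len(parts) == 2:
            out.append((cand, parts[0], parts[1]))
    return out


def _four_connected_parts(pixels: list) -> list:
    remaining = set(pixels)
    parts = []
    while remaining:
        seed = min(remaining)
        stack, comp = [seed], []
        remaining.discard(seed)
        while stack:
            r, c = stack.pop()
            comp.append((r, c))
            for nb in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if nb in remaining:
                    remaining.discard(nb)
                    stack.append(nb)
        parts.append(sorted(comp))
    return parts


def select_extension_point(edges, gray, point: tuple[int, int]):
    """Pick the extension candidate with the largest split contrast.

    Returns ``(candidate, difference)`` where ``difference`` is the absolute
    gap between the mean gray levels of the two background parts, or
    ``None`` when the endpoint has no valid candidate (e.g. jammed against
    the image border).  Ties break to the smallest (row, col).
    """
    img = as_gray(gray)
    cands = candidate_extensions(edges, point)
    best = None
    best_diff = -1.0
    for cand, part_a, part_b in cands:
        mean_a = float(np.mean([img[p] for p in part_a]))
        mean_b = float(np.mean([img[p] for p in part_b]))
        diff = abs(mean_a - mean_b)
        if diff > best_diff:
            best, best_diff = cand, diff
    if best is None:
        return None
    return best, best_diff


def _is_chain_tip(edges: np.ndarray, point: tuple[int, int]) -> bool:
    """True while ``point`` still looks like an open endpoint.

    A freshly added extension pixel has its chain predecessor as one edge
    neighbor (possibly two mutually adjacent ones when the chain turned);
    any additional, non-adjacent edge neighbor means the extension bridged
    into a different edge and the chain must stop.
    """
    h, w = edges.shape
    r, c = point
    nbrs = [
        (r + dr, c + dc)
        for dr, dc in _NEIGHBORS
        if 0 <= r + dr < h and 0 <= c + dc < w and edges[r + dr, c + dc]
    ]
    if len(nbrs) == 1:
        return True
    if len(nbrs) == 2:
        (r1, c1), (r2, c2) = nbrs
        return abs(r1 - r2) + abs(c1 - c2) == 1
    return False


def enforce_edges(edges, gray, params: EnforceParams | None = None) -> np.ndarray:
    """Mend broken edges by iterative endpoint extension.

    Every endpoint of the input map starts a chain.  Each step re-centers on
    the latest extension point; the chain stops when the best candidate's
    split contrast falls below ``params.stop_threshold``, when the new pixel
    touches other edge pixels (two or more edge neighbors: the gap closed),
    or after ``params.max_steps`` steps.  The output contains every input
    edge pixel.
    """
    params = params or EnforceParams()
    out = as_mask(edges).copy()
    img = as_gray(gray)
    # sweep endpoints repeatedly: a chain can create or expose new endpoint
    # configurations, so a single pass is not a fixpoint.  Each sweep either
    # adds at least one pixel or terminates, which bounds the loop.
    while True:
        added = False
        for (r, c), _kind in find_endpoints(out):
            cur = (r, c)
            for _ in range(params.max_steps):
                picked = select_extension_point(out, img, cur)
                if picked is None:
                    break
                cand, diff = picked
                if diff < params.stop_threshold:
                    break
                out[cand] = True
                added = True
                if not _is_chain_tip(out, cand):
                    break  # bridged into another edge: the gap is mended
                cur = cand
        if not added:
            return out
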