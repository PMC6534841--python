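"""Synthetic wound photographs with exact ground truth.

The clinical photographs this method was designed for cannot be shipped, so
every stage is exercised on rendered stand-ins that reproduce the features
the algorithms key on: a skin-toned patch on a non-skin background, a darker
red wound ellipse, plus-shaped suture marks grouped into sites along the
incision, optional wrinkle-line clutter, symptom-specific colorations and
camera noise.  All geometry is recorded as ground truth (wound mask, skin
mask, suture points, site assignment and labels), and a fixed seed renders a
bit-identical image.

What these fixtures do *not* emulate: texture of real tissue, specular
highlights, shadows, perspective, or the full diversity of skin tones —
conclusions drawn from them are about algorithmic behavior, not clinical
performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage import color as skcolor
from scipy import ndimage as ndi
from scipy.ndimage import center_of_mass as ndi_center_of_mass
from skimage import draw as skdraw

from .errors import InvalidInputError
from .infection_classifier import FEATURE_NAMES, LABELS, NORMAL, SYMPTOMS

__all__ = [
    "SyntheticWoundSpec",
    "GroundTruth",
    "make_synthetic_wound",
    "make_palm_image",
    "make_suture_layout",
    "make_feature_table",
    "make_roi_feature_table",
    "hsv_to_rgb255",
]

# capture-condition presets: mild global brightness / white-balance shifts in
# the spirit of photographs from two different phone cameras
_PRESETS = {
    "a": (1.00, (1.00, 1.00, 1.00)),
    "b": (1.06, (1.04, 1.00, 0.95)),
}


def hsv_to_rgb255(h: float, s: float, v: float) -> np.ndarray:
    """Convert one HSV triple (all in [0, 1]) to a uint8 RGB triple."""
    rgb = skcolor.hsv2rgb(np.array([[[h, s, v]]], dtype=float))[0, 0]
    return np.floor(rgb * 255.0 + 0.5).astype(np.uint8)


@dataclass(frozen=True)
class SyntheticWoundSpec:
    """Rendering recipe for one synthetic wound photograph.

    Defaults describe the standard study condition used throughout the test
    suite: a 384x384 frame, a large skin ellipse on a dark drape, a wound
    ellipse of semi-axes (100, 78) and three suture sites of three stitches
    each along the incision axis.
    """

    size: tuple[int, int] = (384, 384)
    skin_hsv: tuple[float, float, float] = (0.07, 0.35, 0.75)
    background_hsv: tuple[float, float, float] = (0.58, 0.50, 0.22)
    wound_hsv: tuple[float, float, float] = (0.97, 0.65, 0.45)
    skin_axes: tuple[float, float] = (172.0, 156.0)
    wound_axes: tuple[float, float] = (100.0, 78.0)
    wound_angle: float | None = None  # radians; None -> random per seed
    n_suture_sites: int = 3
    crosses_per_site: int = 3
    cross_arm: int = 5
    cross_thickness: int = 3
    within_site_spacing: float = 12.0
    site_gap: float = 38.0
    n_wrinkles: int = 0
    wrinkle_contrast: float = 0.10  # median value-channel dip of wrinkle lines
    wrinkle_spread_deg: float = 5.0
    site_labels: tuple[str, ...] | None = None  # None -> all Normal
    noise_sigma: float = 2.0  # RGB units
    preset: str = "a"
    seed: int = 0

    def __post_init__(self):
        if self.preset not in _PRESETS:
            raise InvalidInputError(f"unknown preset {self.preset!r}")
        if self.site_labels is not None:
            if len(self.site_labels) != self.n_suture_sites:
                raise InvalidInputError("site_labels length must equal n_suture_sites")
            bad = set(self.site_labels) - set(LABELS)
            if bad:
                raise InvalidInputError(f"unknown labels: {sorted(bad)}")
        if self.wound_axes[0] >= self.skin_axes[0] or self.wound_axes[1] >= self.skin_axes[1]:
            raise InvalidInputError("wound must fit inside the skin patch")
        if min(self.size) < 4 * self.cross_arm:
            raise InvalidInputError("image too small for the requested crosses")


@dataclass
class GroundTruth:
    """Exact per-pixel and per-point truth for one rendered image."""

    wound_mask: np.ndarray
    skin_mask: np.ndarray
    background_mask: np.ndarray
    suture_points: np.ndarray  # (n, 2) of (row, col)
    site_assignment: np.ndarray  # (n,) site index per point
    site_labels: list[str]
    site_centers: np.ndarray = field(default=None)


def _draw_cross(img: np.ndarray, center: tuple[int, int], arm: int, thick: int, color) -> None:
    r, c = center
    h, w = img.shape[:2]
    t = thick // 2
    r0, r1 = max(r - arm, 0), min(r + arm + 1, h)
    c0, c1 = max(c - arm, 0), min(c + arm + 1, w)
    img[max(r - t, 0) : min(r + t + 1, h), c0:c1] = color
    img[r0:r1, max(c - t, 0) : min(c + t + 1, w)] = color


def make_synthetic_wound(spec: SyntheticWoundSpec | None = None) -> tuple[np.ndarray, GroundTruth]:
    """Render a wound photograph and its ground truth."""
    spec = spec or SyntheticWoundSpec()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    center = (h / 2.0 + rng.uniform(-8, 8), w / 2.0 + rng.uniform(-8, 8))
    angle = rng.uniform(0, np.pi) if spec.wound_angle is None else float(spec.wound_angle)

    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = hsv_to_rgb255(*spec.background_hsv)

    rr, cc = skdraw.ellipse(center[0], center[1], spec.skin_axes[1], spec.skin_axes[0], shape=(h, w))
    skin_full = np.zeros((h, w), dtype=bool)
    skin_full[rr, cc] = True
    img[skin_full] = hsv_to_rgb255(*spec.skin_hsv)

    # the wound ellipse is rotated so its semi-major axis (first of
    # wound_axes) lies along `angle`
    wound_mask = _ellipse_mask((h, w), center, spec.wound_axes, angle)
    img[wound_mask] = hsv_to_rgb255(*spec.wound_hsv)
    skin_mask = skin_full & ~wound_mask

    if spec.n_wrinkles > 0:
        # creases live on intact skin, clear of the wound and of the skin
        # boundary so their edge traces stay separate contours
        wrinkle_zone = ndi.binary_erosion(skin_full, iterations=6) & ~ndi.binary_dilation(
            wound_mask, iterations=8
        )
        _draw_wrinkles(img, wrinkle_zone, spec, rng)

    points, assignment, centers = _place_sites(center, angle, spec, rng)
    labels = list(spec.site_labels) if spec.site_labels is not None else [NORMAL] * spec.n_suture_sites
    _paint_symptoms(img, centers, labels, spec, rng)

    cross_color = np.array([30, 30, 40], dtype=np.uint8)
    for r, c in points:
        _draw_cross(img, (int(r), int(c)), spec.cross_arm, spec.cross_thickness, cross_color)

    gain, wb = _PRESETS[spec.preset]
    out = img.astype(np.float64) * gain * np.array(wb)
    if spec.noise_sigma > 0:
        out = out + rng.normal(0.0, spec.noise_sigma, out.shape)
    out = np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        wound_mask=wound_mask,
        skin_mask=skin_mask,
        background_mask=~skin_full,
        suture_points=np.asarray(points, dtype=int).reshape(-1, 2),
        site_assignment=np.asarray(assignment, dtype=int),
        site_labels=labels,
        site_centers=centers,
    )
    return out, truth


def _ellipse_mask(shape, center, axes, angle) -> np.ndarray:
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w]
    dy = rows - center[0]
    dx = cols - center[1]
    # rotate into ellipse frame: u along the major axis at `angle`
    u = dx * np.cos(angle) + dy * np.sin(angle)
    v = -dx * np.sin(angle) + dy * np.cos(angle)
    a, b = axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _place_sites(center, angle, spec: SyntheticWoundSpec, rng) -> tuple[list, list, np.ndarray]:
    """Suture sites evenly spaced along the incision axis, stitches within."""
    c = spec.n_suture_sites
    m = spec.crosses_per_site
    site_len = (m - 1) * spec.within_site_spacing
    total = c * site_len + (c - 1) * spec.site_gap
    usable = 2 * spec.wound_axes[0] * 0.85
    if total > usable:
        raise InvalidInputError(
            f"suture layout ({total:.0f} px) does not fit along the incision ({usable:.0f} px)"
        )
    direction = np.array([np.sin(angle), np.cos(angle)])  # (row, col) step
    start = -total / 2.0
    points, assignment, centers = [], [], []
    pos = start
    for site in range(c):
        site_positions = [pos + i * spec.within_site_spacing for i in range(m)]
        pos = site_positions[-1] + spec.site_gap
        centers.append(np.array(center) + direction * float(np.mean(site_positions)))
        for sp in site_positions:
            jitter = rng.uniform(-2, 2, size=2)
            pt = np.array(center) + direction * sp + jitter
            points.append((float(pt[0]), float(pt[1])))
            assignment.append(site)
    return points, assignment, np.asarray(centers)


def _draw_wrinkles(img, skin_full, spec: SyntheticWoundSpec, rng) -> None:
    """Near-parallel crease clutter on the skin patch.

    Creases are laid out like real wrinkle fields: non-crossing, roughly
    parallel lines offset along the common normal, with depths drawn from a
    band around ``wrinkle_contrast`` (0.5x to 1.5x) so that raising an edge
    threshold removes them gradually rather than all at once.
    """
    h, w = img.shape[:2]
    base_angle = rng.uniform(0, np.pi)
    direction = np.array([np.sin(base_angle), np.cos(base_angle)])
    normal = np.array([-direction[1], direction[0]])
    centroid = np.array(ndi_center_of_mass(skin_full))
    spacing = 10.0
    offsets = (np.arange(spec.n_wrinkles) - (spec.n_wrinkles - 1) / 2.0) * spacing
    for off in rng.permutation(offsets):
        contrast = spec.wrinkle_contrast * rng.uniform(0.5, 1.5)
        dim = hsv_to_rgb255(
            spec.skin_hsv[0], spec.skin_hsv[1], max(spec.skin_hsv[2] - contrast, 0.0)
        )
        ang = base_angle + np.radians(rng.uniform(-spec.wrinkle_spread_deg, spec.wrinkle_spread_deg))
        seg_dir = np.array([np.sin(ang), np.cos(ang)])
        length = rng.uniform(30, 50)
        mid = centroid + normal * off + direction * rng.uniform(-15, 15)
        p0 = mid - seg_dir * length / 2.0
        p1 = mid + seg_dir * length / 2.0
        r0, c0 = int(np.clip(p0[0], 0, h - 1)), int(np.clip(p0[1], 0, w - 1))
        r1, c1 = int(np.clip(p1[0], 0, h - 1)), int(np.clip(p1[1], 0, w - 1))
        rr, cc = skdraw.line(r0, c0, r1, c1)
        keep = skin_full[rr, cc]
        img[rr[keep], cc[keep]] = dim
        rr2 = np.clip(rr + 1, 0, h - 1)  # 2 px wide so the crease survives smoothing
        keep2 = skin_full[rr2, cc]
        img[rr2[keep2], cc[keep2]] = dim


def _paint_symptoms(img, centers, labels, spec: SyntheticWoundSpec, rng) -> None:
    h, w = img.shape[:2]
    for ctr, label in zip(centers, labels):
        if label == NORMAL:
            continue
        r, c = float(ctr[0]), float(ctr[1])
        if label == "Necrosis":
            rr, cc = skdraw.ellipse(r, c, 12, 16, shape=(h, w))
            img[rr, cc] = (35, 25, 22)
        elif label == "Granulation":
            rr, cc = skdraw.ellipse(r, c, 10, 14, shape=(h, w))
            img[rr, cc] = (205, 60, 55)
        elif label == "Infection":
            rr, cc = skdraw.ellipse(r, c, 13, 17, shape=(h, w))
            img[rr, cc] = (170, 40, 60)
            rr, cc = skdraw.ellipse(r, c, 6, 8, shape=(h, w))
            img[rr, cc] = (210, 180, 90)  # purulent center
        elif label == "Swelling":
            rr, cc = skdraw.ellipse(r, c, 14, 18, shape=(h, w))
            patch = img[rr, cc].astype(np.float64)
            hsv = skcolor.rgb2hsv(patch.reshape(-1, 1, 3) / 255.0)
            hsv[..., 0] = (hsv[..., 0] + 0.06) % 1.0
            hsv[..., 2] = np.clip(hsv[..., 2] * 1.1, 0, 1)
            img[rr, cc] = np.floor(
                skcolor.hsv2rgb(hsv).reshape(-1, 3) * 255.0 + 0.5
            ).astype(np.uint8)


def make_palm_image(
    seed: int = 0,
    n_wrinkles: int = 30,
    wrinkle_contrast: float = 0.10,
    size: tuple[int, int] = (384, 384),
) -> np.ndarray:
    """A wound-free, heavily creased skin patch (palm-like).

    The canonical wrinkle-clutter condition for the upward threshold
    search: a full field of near-parallel creases with mixed depths and no
    wound, so every contour that a threshold raise removes is a crease.
    """
    spec = SyntheticWoundSpec(
        size=size,
        n_wrinkles=n_wrinkles,
        wrinkle_contrast=wrinkle_contrast,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    h, w = size
    center = (h / 2.0 + rng.uniform(-8, 8), w / 2.0 + rng.uniform(-8, 8))
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = hsv_to_rgb255(*spec.background_hsv)
    rr, cc = skdraw.ellipse(center[0], center[1], spec.skin_axes[1], spec.skin_axes[0], shape=(h, w))
    skin_full = np.zeros((h, w), dtype=bool)
    skin_full[rr, cc] = True
    img[skin_full] = hsv_to_rgb255(*spec.skin_hsv)
    zone = ndi.binary_erosion(skin_full, iterations=6)
    _draw_wrinkles(img, zone, spec, rng)
    if spec.noise_sigma > 0:
        noisy = img.astype(np.float64) + rng.normal(0.0, spec.noise_sigma, img.shape)
        img = np.clip(np.floor(noisy + 0.5), 0, 255).astype(np.uint8)
    return img


def make_suture_layout(
    n_sites: int,
    seed: int = 0,
    crosses_per_site: int = 3,
    size: tuple[int, int] = (448, 448),
    within_site_spacing: float = 12.0,
    site_gap: float = 45.0,
) -> tuple[np.ndarray, GroundTruth]:
    """Cross marks grouped into sites on a plain wound-toned canvas.

    A reduced fixture for the ROI-detection stage alone: no skin boundary or
    wound ellipse, just the suture pattern at a random orientation.
    """
    h, w = size
    diag = np.hypot(h, w)
    spec = SyntheticWoundSpec(
        size=size,
        n_suture_sites=n_sites,
        crosses_per_site=crosses_per_site,
        within_site_spacing=within_site_spacing,
        site_gap=site_gap,
        wound_axes=(diag / 2.3, diag / 3.0),
        skin_axes=(diag / 2.0, diag / 2.0),
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    center = (h / 2.0 + rng.uniform(-8, 8), w / 2.0 + rng.uniform(-8, 8))
    angle = rng.uniform(0, np.pi)
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = hsv_to_rgb255(*spec.wound_hsv)
    points, assignment, centers = _place_sites(center, angle, spec, rng)
    cross_color = np.array([30, 30, 40], dtype=np.uint8)
    for r, c in points:
        _draw_cross(img, (int(r), int(c)), spec.cross_arm, spec.cross_thickness, cross_color)
    if spec.noise_sigma > 0:
        noisy = img.astype(np.float64) + rng.normal(0.0, spec.noise_sigma, img.shape)
        img = np.clip(np.floor(noisy + 0.5), 0, 255).astype(np.uint8)
    truth = GroundTruth(
        wound_mask=np.ones((h, w), dtype=bool),
        skin_mask=np.zeros((h, w), dtype=bool),
        background_mask=np.zeros((h, w), dtype=bool),
        suture_points=np.asarray(points, dtype=int).reshape(-1, 2),
        site_assignment=np.asarray(assignment, dtype=int),
        site_labels=[NORMAL] * n_sites,
        site_centers=centers,
    )
    return img, truth


def make_feature_table(
    n_per_class: int, separation: float, seed: int = 0
) -> list[tuple[np.ndarray, str]]:
    """Class-conditional Gaussian feature table over all five labels.

    Class means are placed ``separation`` apart (pairwise, via a scaled
    simplex of random orthonormal directions) with unit within-class
    variance, so ``separation`` is directly the inter-class mean distance in
    within-class standard deviations.  ``separation = 0`` collapses all
    means: features carry no label information.
    """
    if n_per_class < 5:
        raise InvalidInputError("need n_per_class >= 5")
    if separation < 0:
        raise InvalidInputError("separation must be non-negative")
    rng = np.random.default_rng(seed)
    dim = len(FEATURE_NAMES)
    raw = rng.normal(size=(len(LABELS), dim))
    q, _ = np.linalg.qr(raw.T)
    directions = q.T[: len(LABELS)]  # orthonormal rows
    means = directions * (separation / np.sqrt(2.0))  # pairwise distance = separation
    table: list[tuple[np.ndarray, str]] = []
    for mean, label in zip(means, LABELS):
        samples = rng.normal(size=(n_per_class, dim)) + mean
        table.extend((row, label) for row in samples)
    order = rng.permutation(len(table))
    return [table[i] for i in order]


def make_roi_feature_table(
    n_images: int, seed: int = 0, symptom_fraction: float = 0.5
) -> list[tuple[np.ndarray, str]]:
    """Feature vectors computed from rendered fixtures at true site boxes.

    Renders ``n_images`` default wounds whose sites carry random labels
    (each site is symptomatic with probability ``symptom_fraction``), boxes
    each site at its ground-truth center, and computes the standard 17-entry
    feature vector there with the optimum skin color taken as the mean HSV
    of the true skin area.  This is the fixture-distribution training set
    for the symptom classifier.
    """
    from skimage import color as _skcolor

    from .infection_classifier import compute_feature_vector
    from .skin_demarcation import OptimumSkinColor
    from .suture_roi import ROI

    rng = np.random.default_rng(seed)
    table: list[tuple[np.ndarray, str]] = []
    half = 22  # half-size of the site box, px
    for i in range(n_images):
        labels = tuple(
            str(rng.choice(SYMPTOMS)) if rng.random() < symptom_fraction else NORMAL
            for _ in range(3)
        )
        spec = SyntheticWoundSpec(seed=seed * 10000 + i, site_labels=labels)
        img, truth = make_synthetic_wound(spec)
        hsv = _skcolor.rgb2hsv(img)
        sh, ss, sv = hsv[truth.skin_mask].mean(axis=0)
        optm = OptimumSkinColor(float(sh), float(ss), float(sv))
        height, width = img.shape[:2]
        for (cy, cx), label in zip(truth.site_centers, truth.site_labels):
            roi = ROI(
                x_min=max(int(cx) - half, 0),
                y_min=max(int(cy) - half, 0),
                x_max=min(int(cx) + half, width - 1),
                y_max=min(int(cy) + half, height - 1),
                points=np.empty((0, 2)),
            )
            table.append((compute_feature_vector(img, roi, optm), label))
    return table


def default_specs(n: int, base_seed: int = 0, **overrides) -> list[SyntheticWoundSpec]:
    """``n`` default-condition specs with consecutive seeds."""
    return [replace(SyntheticWoundSpec(seed=base_seed + i), **overrides) for i in range(n)]
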