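"""End-to-end orchestration of segmentation and assessment.

``segment_wound`` composes: gray conversion -> Canny + edge enforcement ->
skin demarcation -> candidate/optimized threshold search -> wound
reconstruction.  ``detect_suture_rois`` and ``assess_wound`` continue with
Otsu binarization, cross-feature extraction, hierarchical clustering with
Rosin cluster-count selection, and per-ROI SVM classification.
``evaluate_symptom_predictions`` aggregates predictions against ground
truth into the per-symptom confusion tables used for reporting.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk

from . import suture_roi as sr
from .config import PipelineConfig
from .edge_enforcement import detect_edges, enforce_edges
from .errors import EmptyWoundError, InvalidInputError, NoFeaturePointsError
from .imaging_core import (
    ClassificationCounts,
    as_rgb,
    classification_metrics,
    coverage_metrics,
    rgb_to_gray,
    rgb_to_hsv,
)
from .infection_classifier import (
    SYMPTOMS,
    AssessmentResult,
    TrainedClassifier,
    assess_image,
)
from .skin_demarcation import (
    OptimumSkinColor,
    assign_presence,
    delimit_regions,
    filter_skin_regions,
    optimum_skin_color,
)
from .threshold_optimization import LOW_RATIO, candidate_threshold, optimized_threshold
from .wound_reconstruction import (
    WoundResult,
    complement_wound,
    connect_endpoints,
    skeletonize_and_lines,
)

__all__ = [
    "SegmentationContext",
    "segment_wound",
    "detect_suture_rois",
    "assess_wound",
    "PipelineReport",
    "evaluate_symptom_predictions",
    "coverage_rate_bands",
]


@dataclass
class SegmentationContext:
    """Intermediate products of one segmentation run, kept for auditing."""

    gray: np.ndarray
    hsv: np.ndarray
    enforced_edges: np.ndarray
    skin_mask: np.ndarray
    skin_support: np.ndarray
    optm: OptimumSkinColor
    cand_thr: float
    opt_thr: float
    ae: np.ndarray


def _demarcate(img, gray, hsv, cfg: PipelineConfig):
    edges = detect_edges(gray, LOW_RATIO * cfg.init_threshold, cfg.init_threshold, sigma=cfg.canny_sigma)
    enforced = enforce_edges(edges, gray, cfg.enforce)
    rg = delimit_regions(enforced, close_radius=cfg.close_radius)
    rgp = filter_skin_regions(rg, hsv, cfg.skin_range)
    optm = optimum_skin_color(rgp, hsv, cfg.skin_range)
    skin_mask = assign_presence(rgp, optm, hsv, cfg.presence)
    # support = skin with interior holes (the wound) filled, shrunk by a
    # conservative margin so it never leaks onto the background
    support = ndi.binary_fill_holes(skin_mask)
    if cfg.support_erosion > 0:
        support = ndi.binary_erosion(support, structure=disk(cfg.support_erosion))
    return enforced, skin_mask, support, optm


def segment_wound(img, cfg: PipelineConfig | None = None) -> tuple[WoundResult, SegmentationContext]:
    """Full robust segmentation; returns the wound result and its context."""
    cfg = cfg or PipelineConfig()
    rgb = as_rgb(img)
    gray = rgb_to_gray(rgb)
    hsv = rgb_to_hsv(rgb)

    enforced, skin_mask, support, optm = _demarcate(rgb, gray, hsv, cfg)
    if not support.any():
        raise EmptyWoundError("no skin support found")

    cand = candidate_threshold(gray, cfg.init_threshold, cfg.candidate, cfg.enforce)
    opt = optimized_threshold(gray, rgb, cand, cfg.optimized, cfg.enforce, mask=support)

    ae_full = enforce_edges(
        detect_edges(gray, LOW_RATIO * opt, opt, sigma=cfg.canny_sigma), gray, cfg.enforce
    )
    # wound edges live strictly inside the skin support; edges on the
    # support boundary belong to the skin/background transition
    ae = ae_full & support
    if not ae.any():
        raise EmptyWoundError("no wound edges inside the skin support")

    bb = skeletonize_and_lines(ae, close_radius=cfg.close_radius, hough=cfg.hough)
    bb = connect_endpoints(bb)
    result = complement_wound(
        rgb,
        support,
        bb,
        margin=cfg.margin,
        provenance={
            "init_threshold": cfg.init_threshold,
            "candidate_threshold": cand,
            "optimized_threshold": opt,
            "n_ae_pixels": int(ae.sum()),
        },
    )
    ctx = SegmentationContext(
        gray=gray,
        hsv=hsv,
        enforced_edges=enforced,
        skin_mask=skin_mask,
        skin_support=support,
        optm=optm,
        cand_thr=cand,
        opt_thr=opt,
        ae=ae,
    )
    return result, ctx


def detect_suture_rois(
    wound: WoundResult, cfg: PipelineConfig | None = None
) -> tuple[list[sr.ROI], np.ndarray, int]:
    """Suture-site ROIs within a segmented wound.

    Suture stitches are the darkest marks in the wound area, so the cross
    opening runs on the iterated-Otsu dark class within the wound mask.
    Returns (rois, feature_points, selected_k).
    """
    cfg = cfg or PipelineConfig()
    gray = rgb_to_gray(wound.wound_image)
    dark = sr.binarize_dark_marks(gray, wound.wound_mask)
    crosses = sr.cross_feature_pixels(dark)
    points = sr.extract_feature_points(crosses)
    if len(points) < 2:
        raise NoFeaturePointsError(f"found {len(points)} feature points; need >= 2")
    h = sr.build_hierarchy(points, linkage=cfg.linkage)
    k = sr.select_cluster_count(h, variant=cfg.score_variant)
    rois = sr.detect_rois(h, k, pad=cfg.roi_pad, image_shape=wound.wound_mask.shape)
    return rois, points, k


@dataclass
class PipelineReport:
    """JSON-serializable record of one assessment run."""

    provenance: dict
    n_feature_points: int
    selected_k: int
    rois: list[dict]
    assessment: dict
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineReport":
        return cls(**data)


def assess_wound(
    img, clf: TrainedClassifier, cfg: PipelineConfig | None = None
) -> tuple[PipelineReport, AssessmentResult]:
    """Segment, detect ROIs and classify each suture site."""
    cfg = cfg or PipelineConfig()
    wound, ctx = segment_wound(img, cfg)
    warnings: list[str] = []
    try:
        rois, points, k = detect_suture_rois(wound, cfg)
    except NoFeaturePointsError as exc:
        warnings.append(str(exc))
        rois, points, k = [], np.empty((0, 2), dtype=int), 0
    assessment = assess_image(img, rois, clf, ctx.optm)
    report = PipelineReport(
        provenance=wound.provenance,
        n_feature_points=len(points),
        selected_k=k,
        rois=[roi.to_dict() for roi in rois],
        assessment=assessment.to_dict(),
        warnings=warnings + assessment.warnings,
    )
    return report, assessment


def coverage_rate_bands(rates) -> dict[str, int]:
    """Histogram of coverage rates in the standard reporting bands."""
    edges = [0.9, 0.8, 0.7, 0.6, 0.5]
    names = [">90%", "80%~90%", "70%~80%", "60%~70%", "50%~60%", "<50%"]
    counts = dict.fromkeys(names, 0)
    for rate in rates:
        for name, lo in zip(names, edges):
            if rate > lo:
                counts[name] += 1
                break
        else:
            counts["<50%"] += 1
    return counts


def evaluate_symptom_predictions(
    predicted: list[dict[str, bool]], truth: list[dict[str, bool]]
) -> dict:
    """Per-symptom confusion counts and accuracies over matched image pairs.

    Each image contributes one presence/absence test per symptom, so ``n``
    images yield ``4 n`` symptom tests plus ``n`` anomaly tests (Abnormal =
    any symptom present).
    """
    if len(predicted) != len(truth):
        raise InvalidInputError("prediction/truth counts differ")
    per_symptom = {}
    pooled = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
    for symptom in SYMPTOMS:
        c = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
        for p, t in zip(predicted, truth):
            pv, tv = bool(p.get(symptom, False)), bool(t.get(symptom, False))
            key = ("tp" if tv else "fp") if pv else ("fn" if tv else "tn")
            c[key] += 1
            pooled[key] += 1
        counts = ClassificationCounts(**c)
        per_symptom[symptom] = {"counts": c, **classification_metrics(counts)}
    anomaly = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
    for p, t in zip(predicted, truth):
        pv = any(p.get(s, False) for s in SYMPTOMS)
        tv = any(t.get(s, False) for s in SYMPTOMS)
        key = ("tp" if tv else "fp") if pv else ("fn" if tv else "tn")
        anomaly[key] += 1
    return {
        "n_images": len(predicted),
        "n_symptom_tests": 4 * len(predicted),
        "per_symptom": per_symptom,
        "symptom_overall": {
            "counts": pooled,
            **classification_metrics(ClassificationCounts(**pooled)),
        },
        "anomaly": {
            "counts": anomaly,
            **classification_metrics(ClassificationCounts(**anomaly)),
        },
    }
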