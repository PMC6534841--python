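"""Per-ROI feature vectors and polynomial-kernel SVM symptom assessment.

Each suture-site ROI is summarized by a 17-dimensional color/texture vector
chosen to separate the four clinical symptoms: necrotic tissue is dark
(value channel, dark-pixel fraction), granulation and infection show red hues
and bleeding (redness index, saturated-red fraction), and swelling shifts
the local hue away from the patient's own optimum skin color (hue
deviation).  Two classifier heads are trained on standardized features with
the degree-3 polynomial kernel ``K(x, y) = (gamma <x, y> + r)^d``:

* an anomaly head (Normal vs. Abnormal), and
* four one-vs-rest symptom heads, one per symptom.

Image-level calls aggregate per-ROI predictions: an image is Abnormal when
any ROI is non-Normal, and a symptom is present when any ROI carries it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .edge_enforcement import detect_edges
from .errors import InvalidInputError
from .imaging_core import as_rgb, rgb_to_gray, rgb_to_hsv
from .skin_demarcation import OptimumSkinColor
from .suture_roi import ROI

__all__ = [
    "SYMPTOMS",
    "NORMAL",
    "LABELS",
    "KernelParams",
    "FEATURE_NAMES",
    "compute_feature_vector",
    "polynomial_kernel",
    "TrainedClassifier",
    "train_classifier",
    "AssessmentResult",
    "assess_image",
]

SYMPTOMS = ("Swelling", "Granulation", "Infection", "Necrosis")
NORMAL = "Normal"
LABELS = SYMPTOMS + (NORMAL,)

FEATURE_NAMES = (
    "h_mean", "h_std", "s_mean", "s_std", "v_mean", "v_std",
    "r_mean", "r_std", "g_mean", "g_std", "b_mean", "b_std",
    "redness_index", "dark_fraction", "saturated_red_fraction",
    "edge_density", "hue_deviation",
)


@dataclass(frozen=True)
class KernelParams:
    """Polynomial kernel parameters; degree 3 by default."""

    gamma: float = 1.0 / len(FEATURE_NAMES)
    r: float = 1.0
    degree: int = 3
    C: float = 1.0

    def __post_init__(self):
        if self.gamma <= 0:
            raise InvalidInputError("gamma must be positive")
        if self.r < 0:
            raise InvalidInputError("r must be non-negative")
        if self.degree < 1 or int(self.degree) != self.degree:
            raise InvalidInputError("degree must be a positive integer")
        if self.C <= 0:
            raise InvalidInputError("C must be positive")


def polynomial_kernel(x, y, params: KernelParams | None = None) -> float:
    """Evaluate ``(gamma <x, y> + r)^d`` for two feature vectors."""
    params = params or KernelParams()
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise InvalidInputError("x and y must be 1-D vectors of equal length")
    return float((params.gamma * xv @ yv + params.r) ** params.degree)


def compute_feature_vector(
    img, roi: ROI, optm: OptimumSkinColor | None = None
) -> np.ndarray:
    """17-feature color/texture summary of one ROI (see FEATURE_NAMES).

    RGB statistics are on the 0-255 scale, HSV statistics on [0, 1].  The
    redness index is ``mean(R - (G + B)/2) / 255``; the dark fraction counts
    pixels with V < 0.2 and the saturated-red fraction pixels with hue near
    0 or 1 and saturation > 0.5.  Edge density is the Canny edge fraction
    inside the ROI; hue deviation is the distance of the mean hue from the
    image's optimum skin hue (0 when no optimum is available).
    """
    arr = as_rgb(img)
    hgt, wid = arr.shape[:2]
    if not (0 <= roi.x_min <= roi.x_max < wid and 0 <= roi.y_min <= roi.y_max < hgt):
        raise InvalidInputError("ROI outside image bounds")
    patch = arr[roi.y_min : roi.y_max + 1, roi.x_min : roi.x_max + 1]
    if patch.shape[0] * patch.shape[1] < 4:
        raise InvalidInputError("ROI smaller than 4 pixels")
    hsv = rgb_to_hsv(patch)
    rgb = patch.astype(np.float64)

    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    redness = float((r - (g + b) / 2.0).mean() / 255.0)
    dark_fraction = float((v < 0.2).mean())
    satred = float((((h < 0.05) | (h > 0.95)) & (s > 0.5)).mean())
    edges = detect_edges(rgb_to_gray(patch), 20.0, 50.0)
    hue_dev = float(abs(h.mean() - optm.sh_optm)) if optm is not None else 0.0

    return np.array(
        [
            h.mean(), h.std(), s.mean(), s.std(), v.mean(), v.std(),
            r.mean(), r.std(), g.mean(), g.std(), b.mean(), b.std(),
            redness, dark_fraction, satred,
            float(edges.mean()), hue_dev,
        ]
    )


@dataclass
class TrainedClassifier:
    """Standardizer plus anomaly and per-symptom SVM heads."""

    scaler: StandardScaler
    anomaly: SVC
    symptom_heads: dict[str, SVC]
    kernel: KernelParams
    feature_names: tuple = FEATURE_NAMES
    version: str = "1"
    meta: dict = field(default_factory=dict)

    def predict_rois(self, vectors: np.ndarray) -> list[str]:
        """One label per ROI: the decisive symptom head, else Normal."""
        x = self.scaler.transform(np.asarray(vectors, dtype=float))
        out = []
        for row in x:
            row = row.reshape(1, -1)
            scores = {
                name: float(head.decision_function(row)[0])
                for name, head in self.symptom_heads.items()
            }
            positive = {n: sc for n, sc in scores.items() if sc > 0}
            if positive:
                out.append(max(sorted(positive), key=lambda n: positive[n]))
            else:
                out.append(NORMAL)
        return out

    def predict_anomaly(self, vectors: np.ndarray) -> np.ndarray:
        x = self.scaler.transform(np.asarray(vectors, dtype=float))
        return self.anomaly.predict(x).astype(bool)

    def save(self, path) -> None:
        joblib.dump({"format": "woundkit-classifier", "version": self.version, "model": self}, path)

    @classmethod
    def load(cls, path) -> "TrainedClassifier":
        payload = joblib.load(path)
        if payload.get("format") != "woundkit-classifier":
            raise InvalidInputError(f"{path} is not a woundkit classifier file")
        return payload["model"]


def train_classifier(
    table, params: KernelParams | None = None, seed: int = 0
) -> TrainedClassifier:
    """Fit the anomaly and symptom heads from (vector, label) pairs.

    Labels must come from :data:`LABELS` with at least two classes and five
    samples per present class.  Class imbalance is handled with
    inverse-frequency ("balanced") class weights.
    """
    params = params or KernelParams()
    vectors = np.asarray([np.asarray(v, dtype=float) for v, _ in table])
    labels = np.asarray([lab for _, lab in table])
    classes, counts = np.unique(labels, return_counts=True)
    unknown = set(classes) - set(LABELS)
    if unknown:
        raise InvalidInputError(f"unknown labels: {sorted(unknown)}")
    if len(classes) < 2:
        raise InvalidInputError("need at least two classes to train")
    if counts.min() < 5:
        raise InvalidInputError("need at least 5 samples per class")

    scaler = StandardScaler().fit(vectors)
    x = scaler.transform(vectors)

    def make_svc():
        return SVC(
            kernel="poly",
            degree=params.degree,
            gamma=params.gamma,
            coef0=params.r,
            C=params.C,
            class_weight="balanced",
            random_state=seed,
        )

    anomaly = make_svc().fit(x, labels != NORMAL)
    heads = {}
    for symptom in SYMPTOMS:
        target = labels == symptom
        if target.any() and not target.all():
            heads[symptom] = make_svc().fit(x, target)
    return TrainedClassifier(
        scaler=scaler,
        anomaly=anomaly,
        symptom_heads=heads,
        kernel=params,
        meta={"n_train": len(labels), "classes": {c: int(n) for c, n in zip(classes, counts)}},
    )


@dataclass
class AssessmentResult:
    """Per-ROI labels with image-level anomaly and symptom flags."""

    roi_labels: list[str]
    anomaly: bool
    symptom_flags: dict[str, bool]
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "roi_labels": list(self.roi_labels),
            "anomaly": self.anomaly,
            "symptom_flags": dict(self.symptom_flags),
            "warnings": list(self.warnings),
        }


def assess_image(
    img,
    rois: list[ROI],
    clf: TrainedClassifier,
    optm: OptimumSkinColor | None = None,
) -> AssessmentResult:
    """Classify every ROI and aggregate to image-level flags.

    With no ROIs the image is reported Normal with an explicit warning (no
    suture sites means nothing to assess).
    """
    if not rois:
        return AssessmentResult(
            roi_labels=[],
            anomaly=False,
            symptom_flags={s: False for s in SYMPTOMS},
            warnings=["no suture sites found; defaulting to Normal"],
        )
    vectors = np.asarray([compute_feature_vector(img, roi, optm) for roi in rois])
    roi_labels = clf.predict_rois(vectors)
    flags = {s: any(lab == s for lab in roi_labels) for s in SYMPTOMS}
    return AssessmentResult(
        roi_labels=roi_labels,
        anomaly=any(lab != NORMAL for lab in roi_labels),
        symptom_flags=flags,
    )
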