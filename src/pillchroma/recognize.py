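"""Surrogate pill recognizer: interpretable features + nearest class mean.

Stands in for the study-scale CNN so the accuracy-versus-colour-difference
analysis can run on a desk. Each segmented ROI is reduced to a fixed
feature vector — mean CIE L*a*b* colour, scale-invariant shape
descriptors and an imprint score — and classified by nearest class mean
in standardized feature space, with top-k evaluation per imaging
condition. Any classifier implementing the PillClassifier protocol can
be plugged in instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Protocol, Sequence

import numpy as np
from skimage import measure

from .color import WhitePoint, rgb_to_lab, roi_mean_color

#: feature vector layout (fixed dimensionality)
FEATURE_NAMES = (
    "L", "a", "b",
    "area_frac", "aspect_ratio", "circularity",
    "hu1", "hu2", "hu3", "hu4",
    "imprint_score",
)


@dataclass(frozen=True)
class TopKResult:
    """Top-k accuracy of one condition's test set."""

    condition_name: str
    k: int
    accuracy: float
    n_eval: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")


def _log_hu(hu: np.ndarray) -> np.ndarray:
    """Log-compressed Hu moments; sign-preserving, finite for zeros."""
    return -np.sign(hu) * np.log10(np.abs(hu) + 1e-30)


def featurize(roi: np.ndarray, mask: np.ndarray,
              white: WhitePoint | None = None) -> np.ndarray:
    """Deterministic feature vector for one segmented ROI.

    Shape descriptors are derived from the mask alone and are invariant
    to uniform rescaling (area fraction, aspect ratio, circularity via
    4πA/P², log Hu moments); the colour block is the mean ROI colour in
    L*a*b*; the imprint score is the fraction of pill pixels markedly
    darker than the pill's median luminance.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    lab = rgb_to_lab(roi_mean_color(roi, mask), white)

    props = measure.regionprops(mask.astype(np.uint8))[0]
    area = props.area
    area_frac = area / mask.size
    minor = max(props.axis_minor_length, 1e-9)
    aspect = props.axis_major_length / minor
    # Crofton perimeter: digitization-corrected, stable under rescaling
    perimeter = max(measure.perimeter_crofton(mask, directions=2), 1e-9)
    circularity = 4.0 * np.pi * area / perimeter ** 2
    hu = _log_hu(props.moments_hu[:4])

    gray = np.asarray(roi, dtype=float) @ np.array([0.299, 0.587, 0.114])
    pill = gray[mask]
    med = np.median(pill)
    imprint_score = float(np.mean(pill < 0.8 * med)) if med > 0 else 0.0

    vec = np.array([lab[0], lab[1], lab[2], area_frac, aspect, circularity,
                    *hu, imprint_score], dtype=float)
    if not np.all(np.isfinite(vec)):
        raise ValueError("non-finite feature encountered")
    return vec


class PillClassifier(Protocol):
    """Plug-in interface: anything that ranks labels for a feature vector."""

    def predict_topk(self, fv: np.ndarray, k: int) -> list[int]: ...


@dataclass
class NearestClassMeanModel:
    """Nearest class mean in per-dimension standardized feature space.

    Training is order-independent (means and scales are symmetric in the
    samples); distance ties are broken toward the lowest label.
    """

    labels: np.ndarray        # sorted unique labels
    class_means: np.ndarray   # len(labels) × d, standardized space
    feature_mean: np.ndarray  # d
    feature_scale: np.ndarray # d

    def _standardize(self, fv: np.ndarray) -> np.ndarray:
        return (np.asarray(fv, dtype=float) - self.feature_mean) / self.feature_scale

    def predict_topk(self, fv: np.ndarray, k: int) -> list[int]:
        """The k labels nearest to fv, ascending distance, ties by label."""
        if not 1 <= k <= len(self.labels):
            raise ValueError(f"k must be in 1..{len(self.labels)}, got {k}")
        d = np.linalg.norm(self.class_means - self._standardize(fv), axis=1)
        order = np.lexsort((self.labels, d))
        return [int(self.labels[i]) for i in order[:k]]

    def to_json(self) -> str:
        return json.dumps({
            "labels": self.labels.tolist(),
            "class_means": self.class_means.tolist(),
            "feature_mean": self.feature_mean.tolist(),
            "feature_scale": self.feature_scale.tolist(),
            "feature_names": list(FEATURE_NAMES),
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "NearestClassMeanModel":
        d = json.loads(text)
        return cls(labels=np.asarray(d["labels"]),
                   class_means=np.asarray(d["class_means"]),
                   feature_mean=np.asarray(d["feature_mean"]),
                   feature_scale=np.asarray(d["feature_scale"]))


def fit_classifier(training: Sequence[tuple[np.ndarray, int]],
                   expected_labels: Sequence[int] | None = None,
                   ) -> NearestClassMeanModel:
    """Fit the nearest-class-mean model from (feature vector, label) pairs.

    When expected_labels is given, every one of them must be covered by
    at least one training example (raises ValueError otherwise).
    """
    if not training:
        raise ValueError("empty training set")
    X = np.stack([fv for fv, _ in training]).astype(float)
    y = np.array([label for _, label in training])
    labels = np.unique(y)
    if expected_labels is not None:
        missing = sorted(set(expected_labels) - set(labels.tolist()))
        if missing:
            raise ValueError(f"no training examples for labels {missing}")

    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale < 1e-9, 1.0, scale)
    Z = (X - mean) / scale
    class_means = np.stack([Z[y == lab].mean(axis=0) for lab in labels])
    return NearestClassMeanModel(labels=labels, class_means=class_means,
                                 feature_mean=mean, feature_scale=scale)


def evaluate_topk(model: PillClassifier,
                  test_records: Iterable[tuple[np.ndarray, int, str]],
                  ks: Sequence[int] = (1, 5)) -> list[TopKResult]:
    """Top-k accuracy per condition.

    test_records yields (feature vector, true label, condition name);
    a record with fv=None (segmentation failure upstream) counts as a
    miss at every k. Results are ordered by condition then k.
    """
    per_condition: dict[str, list[list[int] | None]] = {}
    truth: dict[str, list[int]] = {}
    kmax = max(ks)
    n_total = 0
    for fv, label, cond in test_records:
        n_total += 1
        ranked = model.predict_topk(fv, kmax) if fv is not None else None
        per_condition.setdefault(cond, []).append(ranked)
        truth.setdefault(cond, []).append(label)
    if n_total == 0:
        raise ValueError("empty test set")

    results = []
    for cond in per_condition:
        ranked_lists = per_condition[cond]
        labels = truth[cond]
        for k in ks:
            hits = sum(1 for ranked, lab in zip(ranked_lists, labels)
                       if ranked is not None and lab in ranked[:k])
            results.append(TopKResult(condition_name=cond, k=k,
                                      accuracy=hits / len(labels),
                                      n_eval=len(labels)))
    return results
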