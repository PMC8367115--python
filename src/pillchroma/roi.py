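"""Pill segmentation: grayscale → blur/threshold → Canny → fill → crop.

Mirrors the photographic preprocessing used to isolate a single pill
from its field before recognition: the frame is converted to grayscale,
blurred and thresholded; Canny edges of the pill outline are closed and
filled to a solid region; the original frame is masked to the region and
cropped to a square window around it. When the contour route finds no
closed outline (low-contrast scenes), the thresholded mask is the
documented fallback; if both routes fail the caller gets a
SegmentationError naming the stage rather than a garbage crop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import feature, filters, measure, morphology

#: ITU-R BT.601 luma weights for the grayscale conversion
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


class SegmentationError(RuntimeError):
    """Segmentation failed; `stage` names where."""

    def __init__(self, message: str, stage: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class DegenerateImageError(SegmentationError):
    """Image has no separable intensity classes (e.g. constant frame)."""

    def __init__(self, message: str):
        super().__init__(message, stage="binarize")


@dataclass(frozen=True)
class BoundingBox:
    """Half-open pixel box [row_min, row_max) × [col_min, col_max),
    row-major with origin at the top-left corner."""

    row_min: int
    col_min: int
    row_max: int
    col_max: int

    def __post_init__(self) -> None:
        if not (0 <= self.row_min < self.row_max and 0 <= self.col_min < self.col_max):
            raise ValueError(f"degenerate bounding box {self}")

    @property
    def height(self) -> int:
        return self.row_max - self.row_min

    @property
    def width(self) -> int:
        return self.col_max - self.col_min


@dataclass(frozen=True)
class RoiConfig:
    """Knobs of the extraction chain (8-bit Canny thresholds).

    canny_source selects the input of the edge detector: the blurred
    grayscale frame ("gray", default) or the thresholded mask
    ("binary") — both wirings of the published step order.
    """

    blur_radius: float = 2.0
    canny_low: float = 50.0
    canny_high: float = 150.0
    canny_sigma: float = 1.0
    canny_source: str = "gray"
    pad: int = 4
    min_area_frac: float = 0.005
    max_area_frac: float = 0.95


@dataclass
class RoiResult:
    """Extraction output: the square ROI crop, the full-frame mask,
    the crop window and which strategy produced the mask."""

    roi: np.ndarray            # S×S×3 uint8, black outside the pill
    mask: np.ndarray           # H×W bool in frame coordinates
    roi_mask: np.ndarray       # S×S bool, mask cropped to the ROI window
    bbox: BoundingBox
    strategy: str              # "contour" or "threshold"
    fallback_used: bool


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """BT.601 luma of an 8-bit RGB frame, rounded back to uint8."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3 or image.size == 0:
        raise ValueError(f"expected nonempty H×W×3 image, got shape {image.shape}")
    return np.rint(image.astype(float) @ LUMA_WEIGHTS).astype(np.uint8)


def binarize(gray: np.ndarray, blur_radius: float = 2.0,
             method: str = "otsu") -> np.ndarray:
    """Gaussian blur then global threshold, foreground = pill side.

    Polarity is auto-selected from border statistics: the image border
    is assumed to be background, so the foreground is whichever side of
    the threshold the border does *not* fall on. Raises
    DegenerateImageError on constant images.
    """
    gray = np.asarray(gray, dtype=float)
    if blur_radius < 0:
        raise ValueError("blur_radius must be ≥ 0")
    blurred = filters.gaussian(gray, sigma=blur_radius, preserve_range=True)
    if np.ptp(blurred) < 1e-9:
        raise DegenerateImageError("constant image: no separable classes")
    if method == "otsu":
        thresh = filters.threshold_otsu(blurred)
    elif method == "mean":
        thresh = blurred.mean()
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    border = np.concatenate([blurred[0], blurred[-1], blurred[:, 0], blurred[:, -1]])
    if border.mean() > thresh:
        mask = blurred < thresh   # dark pill on bright field
    else:
        mask = blurred >= thresh  # bright pill on dark field
    if not mask.any() or mask.all():
        raise DegenerateImageError("threshold produced a single class")
    return mask


def trace_and_fill(edges_src: np.ndarray, canny_low: float = 50.0,
                   canny_high: float = 150.0, sigma: float = 1.0) -> np.ndarray:
    """Canny edge map → close the outer contour → flood-fill its interior.

    Returns the filled outer region (largest connected component);
    nested inner contours such as imprints are swallowed by the fill.
    Raises SegmentationError when no closed contour encloses any area.
    """
    if canny_low >= canny_high:
        raise ValueError("canny_low must be < canny_high")
    src = np.asarray(edges_src, dtype=float) / 255.0
    edges = feature.canny(src, sigma=sigma,
                          low_threshold=canny_low / 255.0,
                          high_threshold=canny_high / 255.0)
    if not edges.any():
        raise SegmentationError("no edges detected", stage="canny")
    closed = morphology.closing(edges, footprint=morphology.disk(2))
    filled = ndimage.binary_fill_holes(closed)
    interior = filled & ~closed
    if interior.sum() < 0.5 * closed.sum() or interior.sum() < 16:
        raise SegmentationError("no closed contour to fill", stage="fill")
    labels = measure.label(filled)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return labels == largest


def mask_and_crop(original: np.ndarray, mask: np.ndarray,
                  pad: int = 4) -> tuple[np.ndarray, BoundingBox, np.ndarray]:
    """Black out everything outside the mask and crop a square window.

    The tight bounding box is padded, then its short side is expanded
    symmetrically to a square; a window clipped by the frame border is
    shifted inward before being shrunk, so the crop is always square
    (side ≤ min(H, W)). Returns (roi, bbox, roi_mask).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise SegmentationError("empty mask", stage="crop")
    h, w = mask.shape
    masked = np.asarray(original).copy()
    masked[~mask] = 0

    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = rows[0] - pad, rows[-1] + 1 + pad
    c0, c1 = cols[0] - pad, cols[-1] + 1 + pad
    side = min(max(r1 - r0, c1 - c0), h, w)

    def _fit(lo: int, hi: int, limit: int) -> tuple[int, int]:
        grow = side - (hi - lo)
        lo -= grow // 2
        hi += grow - grow // 2
        if lo < 0:
            hi -= lo
            lo = 0
        if hi > limit:
            lo -= hi - limit
            hi = limit
        return max(lo, 0), hi

    r0, r1 = _fit(int(r0), int(r1), h)
    c0, c1 = _fit(int(c0), int(c1), w)
    bbox = BoundingBox(int(r0), int(c0), int(r1), int(c1))
    return masked[r0:r1, c0:c1], bbox, mask[r0:r1, c0:c1]


def extract_roi(image: np.ndarray, config: RoiConfig | None = None) -> RoiResult:
    """Full extraction chain with the documented contour→threshold fallback.

    The contour-fill mask is preferred; it is rejected (falling back to
    the threshold mask) when it covers an implausible area fraction of
    the frame. If both strategies fail a SegmentationError names the
    failing stage.
    """
    config = config or RoiConfig()
    gray = to_grayscale(image)
    thresh_mask = binarize(gray, blur_radius=config.blur_radius)  # may raise

    h, w = gray.shape
    lo, hi = config.min_area_frac * h * w, config.max_area_frac * h * w

    def _plausible(m: np.ndarray) -> bool:
        return lo <= m.sum() <= hi

    blurred = filters.gaussian(gray.astype(float), sigma=config.blur_radius,
                               preserve_range=True)
    edge_src = (thresh_mask.astype(float) * 255.0
                if config.canny_source == "binary" else blurred)

    mask, strategy = None, "contour"
    try:
        candidate = trace_and_fill(edge_src, config.canny_low,
                                   config.canny_high, config.canny_sigma)
        if _plausible(candidate):
            mask = candidate
    except SegmentationError:
        pass

    fallback = mask is None
    if fallback:
        strategy = "threshold"
        labels = measure.label(thresh_mask)
        largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
        candidate = labels == largest
        if _plausible(candidate):
            mask = ndimage.binary_fill_holes(candidate)
    if mask is None:
        raise SegmentationError("both contour and threshold masks implausible",
                                stage="threshold-fallback")

    roi, bbox, roi_mask = mask_and_crop(image, mask, pad=config.pad)
    return RoiResult(roi=roi, mask=mask, roi_mask=roi_mask, bbox=bbox,
                     strategy=strategy, fallback_used=fallback)


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection-over-union of two boolean masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)
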