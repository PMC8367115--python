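"""RGB → XYZ → CIE L*a*b* conversion and ΔE*ab colour differences.

The conversion chain quantifies how far a pill's photographed colour
drifts from its reference-condition colour. RGB channels are normalised
to [0, 1] and mapped linearly to XYZ with the study's 3×3 matrix (whose
middle row sums to 1, so Y(white) = 1), then to L*a*b* with the CIE 1976
equations

    L* = 116 f(Y/Yn) − 16
    a* = 500 (f(X/Xn) − f(Y/Yn))
    b* = 200 (f(Y/Yn) − f(Z/Zn))

where f(q) = q^(1/3) above q = 0.008856 and 7.787 q + 16/116 below.
The default reference white is *white-anchored*: (Xn, Yn, Zn) is the
image of RGB white under the same matrix, so L* spans exactly [0, 100]
over the in-gamut RGB cube. ΔE*ab is the Euclidean distance in L*a*b*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

#: RGB→XYZ matrix, rows X, Y, Z (applied to channels scaled to [0, 1]).
RGB_TO_XYZ = np.array([
    [0.4303, 0.3416, 0.1784],
    [0.2219, 0.7068, 0.0713],
    [0.0202, 0.1296, 0.9393],
])

#: knee of the piecewise f(q)
_Q_KNEE = 0.008856


@dataclass(frozen=True)
class WhitePoint:
    """Normalising white (Xn, Yn, Zn) for the XYZ→Lab step."""

    xn: float
    yn: float
    zn: float

    def __post_init__(self) -> None:
        if min(self.xn, self.yn, self.zn) <= 0:
            raise ValueError("white point components must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.xn, self.yn, self.zn])


def anchored_white() -> WhitePoint:
    """White point anchored to the conversion matrix: rgb_to_xyz(1,1,1)."""
    x, y, z = RGB_TO_XYZ.sum(axis=1)
    return WhitePoint(float(x), float(y), float(z))


#: CIE D65 2° standard illuminant, selectable via config
D65_WHITE = WhitePoint(0.95047, 1.0, 1.08883)

WHITEPOINTS = {"anchored": anchored_white, "d65": lambda: D65_WHITE}


@dataclass(frozen=True)
class LabColor:
    L: float
    a: float
    b: float


@dataclass(frozen=True)
class DeltaERecord:
    """Colour difference of one pill under one condition vs its reference."""

    pill_label: int
    condition_name: str
    delta_e: float
    n_images: int

    def __post_init__(self) -> None:
        if self.delta_e < 0:
            raise ValueError("delta_e must be nonnegative")


def rgb_to_xyz(rgb: Sequence[float] | np.ndarray) -> np.ndarray:
    """Linear map of [0,1] RGB to XYZ. Accepts a triple or an (..., 3) array."""
    arr = np.asarray(rgb, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("expected 3 channels")
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("RGB channels must lie in [0, 1]")
    return arr @ RGB_TO_XYZ.T


def lab_f(q):
    """Piecewise lightness compression: cube root above the knee,
    7.787·q + 16/116 below; continuous at q = 0.008856 within 1e-4."""
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("f(q) requires q ≥ 0")
    out = np.where(q > _Q_KNEE, np.cbrt(q), 7.787 * q + 16.0 / 116.0)
    return float(out) if out.ndim == 0 else out


def xyz_to_lab(xyz: Sequence[float] | np.ndarray,
               white: WhitePoint | None = None) -> np.ndarray:
    """CIE 1976 L*a*b* from XYZ. Accepts a triple or an (..., 3) array;
    returns the same shape with channels (L*, a*, b*)."""
    white = white or anchored_white()
    arr = np.asarray(xyz, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("expected 3 components")
    fx, fy, fz = np.moveaxis(lab_f(arr / white.as_array()), -1, 0)
    L = 116.0 * fy - 16.0
    a = 500.0 * (fx - fy)
    b = 200.0 * (fy - fz)
    return np.stack([L, a, b], axis=-1)


def rgb_to_lab(rgb, white: WhitePoint | None = None) -> np.ndarray:
    """Composition of the two conversion steps."""
    return xyz_to_lab(rgb_to_xyz(rgb), white)


def delta_e(p, q) -> float | np.ndarray:
    """Euclidean ΔE*ab between two Lab colours (or arrays of them)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    d = np.sqrt(np.sum((p - q) ** 2, axis=-1))
    return float(d) if d.ndim == 0 else d


def roi_mean_color(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Mean RGB over the masked pill region, scaled to [0, 1].

    Mirrors the mean-channel workflow of ImageJ-style RGB analysis:
    one average colour per region of interest, not per-pixel statistics.
    """
    mask = np.asarray(mask, dtype=bool)
    if image.shape[:2] != mask.shape:
        raise ValueError("image and mask dimensions differ")
    if not mask.any():
        raise ValueError("empty mask")
    return image[mask].mean(axis=0) / 255.0


def condition_delta_e(reference_records: Iterable[tuple[int, np.ndarray]],
                      condition_records: Iterable[tuple[int, str, np.ndarray]],
                      white: WhitePoint | None = None) -> list[DeltaERecord]:
    """Per-(pill, condition) ΔE vs the reference condition.

    reference_records: (pill label, mean ROI rgb in [0,1]) per reference
    image; condition_records: (label, condition name, mean ROI rgb) per
    real-world image. For each pill the reference Lab is the average Lab
    over its reference replicates; ΔE is computed per condition replicate
    against that anchor and averaged, giving one record per cell.
    """
    white = white or anchored_white()
    ref_labs: dict[int, list[np.ndarray]] = {}
    for label, rgb in reference_records:
        ref_labs.setdefault(label, []).append(rgb_to_lab(rgb, white))
    ref_anchor = {label: np.mean(labs, axis=0) for label, labs in ref_labs.items()}

    cells: dict[tuple[int, str], list[float]] = {}
    for label, cond, rgb in condition_records:
        if label not in ref_anchor:
            raise ValueError(f"no reference images for pill {label}")
        de = delta_e(rgb_to_lab(rgb, white), ref_anchor[label])
        cells.setdefault((label, cond), []).append(float(de))

    return [DeltaERecord(pill_label=label, condition_name=cond,
                         delta_e=float(np.mean(des)), n_images=len(des))
            for (label, cond), des in cells.items()]
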