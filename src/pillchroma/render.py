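"""Synthetic pill photography with ground-truth masks and colours.

Renders one pill per frame on a black or white field under a simple
radiometric camera model:

    scene = base_rgb/255 · auto_gain(background) [pill pixels]
          | background level                     [field pixels]
    scene → ×flash_gain, +specular highlight     (flash on)
    scene → ×2^EV                                (exposure compensation)
    scene → +N(0, σ/255)                         (sensor noise)
    image = clip(round(255·scene), 0, 255)

EV follows photographic-stop semantics: +1 EV doubles captured light.
The auto-exposure coupling emulates a camera metering the whole frame:
pill brightness shifts opposite to background brightness, anchored so
that the reference condition (black background, flash off, EV 0)
reproduces the pill's true surface colour exactly up to quantisation.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

from .catalog import ConditionSpec, PillClass, condition_grid, reference_condition


class SizingError(ValueError):
    """Canvas too small to hold the pill at the requested area fraction."""


@dataclass(frozen=True)
class RenderParams:
    """Tunable parameters of the camera/scene model.

    noise_sigma is the additive sensor-noise SD in 8-bit counts;
    area_fraction is the mean fraction of the canvas the pill covers
    (jittered per image within [0.2, 0.6]); auto_exposure_coeff scales
    the metering coupling between background level and pill gain.
    """

    noise_sigma: float = 2.0
    bg_black: float = 0.02
    bg_white: float = 0.98
    auto_exposure_coeff: float = 0.25
    flash_gain: float = 1.15
    flash_strength: float = 0.35
    flash_sigma_frac: float = 0.45
    area_fraction: float = 0.35
    area_jitter: float = 0.05
    imprint_depth: float = 0.3
    imprint_area_frac: float = 0.012


@dataclass
class ImageRecord:
    """One rendered frame plus its ground truth."""

    image: np.ndarray          # H×W×3 uint8
    label: int
    condition: str
    truth_mask: np.ndarray     # H×W bool, the pill region
    truth_rgb: tuple[float, float, float]  # mean surface colour, 0..255 scale
    seed: int


def _shape_mask(shape: str, area: float, hw: tuple[int, int],
                center: tuple[float, float], angle: float) -> np.ndarray:
    """Boolean mask of a convex pill silhouette with the given area."""
    h, w = hw
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    dv, du = rr - center[0], cc - center[1]
    # rotate coordinates into the pill frame
    u = du * np.cos(angle) + dv * np.sin(angle)
    v = -du * np.sin(angle) + dv * np.cos(angle)

    if shape == "round":
        r = np.sqrt(area / np.pi)
        return u * u + v * v <= r * r
    if shape == "oval":
        ratio = 1.4
        b = np.sqrt(area / (np.pi * ratio))
        a = ratio * b
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if shape in ("oblong", "capsule"):
        # stadium: rectangle of length ell and half-width r with
        # semicircular caps; total length / width = elongation
        elong = 2.0 if shape == "oblong" else 2.8
        r = np.sqrt(area / ((2 * elong - 2) * 2 + np.pi))
        ell = (2 * elong - 2) * r
        ax = np.clip(np.abs(u) - ell / 2, 0, None)
        return ax * ax + v * v <= r * r
    if shape in ("triangle", "pentagon"):
        n = 3 if shape == "triangle" else 5
        circ_r = np.sqrt(2 * area / (n * np.sin(2 * np.pi / n)))
        apothem = circ_r * np.cos(np.pi / n)
        inside = np.ones((h, w), dtype=bool)
        for k in range(n):
            th = 2 * np.pi * k / n
            inside &= u * np.cos(th) + v * np.sin(th) <= apothem
        return inside
    if shape == "diamond":
        ratio = 1.3
        b = np.sqrt(area / (2 * ratio))
        a = ratio * b
        return np.abs(u) / a + np.abs(v) / b <= 1.0
    raise ValueError(f"unknown shape {shape!r}")


def _shape_extent(shape: str, area: float) -> float:
    """Circumscribed radius of the silhouette, for canvas-fit checks."""
    if shape == "round":
        return np.sqrt(area / np.pi)
    if shape == "oval":
        return np.sqrt(area * 1.4 / np.pi)
    if shape in ("oblong", "capsule"):
        elong = 2.0 if shape == "oblong" else 2.8
        r = np.sqrt(area / ((2 * elong - 2) * 2 + np.pi))
        return elong * r
    if shape in ("triangle", "pentagon"):
        n = 3 if shape == "triangle" else 5
        return np.sqrt(2 * area / (n * np.sin(2 * np.pi / n)))
    if shape == "diamond":
        return np.sqrt(area * 1.3 / 2)
    raise ValueError(f"unknown shape {shape!r}")


def _imprint_mask(mask: np.ndarray, center: tuple[float, float], angle: float,
                  area: float, frac: float) -> np.ndarray:
    """Thin embossed bar through the pill centre covering ≈frac of its area."""
    h, w = mask.shape
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    dv, du = rr - center[0], cc - center[1]
    u = du * np.cos(angle) + dv * np.sin(angle)
    v = -du * np.sin(angle) + dv * np.cos(angle)
    r_eff = np.sqrt(area / np.pi)
    half_len = 0.45 * r_eff
    half_thick = max(frac * area / (4 * half_len), 0.6)
    return mask & (np.abs(u) <= half_len) & (np.abs(v) <= half_thick)


def render_image(pill: PillClass, condition: ConditionSpec,
                 canvas_size: tuple[int, int] = (128, 128), seed: int = 0,
                 params: RenderParams | None = None) -> ImageRecord:
    """Render one pill under one condition, fully reproducible from seed.

    Raises SizingError when the canvas is below 64×64 or cannot hold the
    pill at the minimum area fraction (20% of the canvas).
    """
    params = params or RenderParams()
    h, w = canvas_size
    if h < 64 or w < 64:
        raise SizingError(f"canvas {canvas_size} below minimum 64×64")

    rng = np.random.default_rng(seed)
    frac = float(np.clip(params.area_fraction + rng.normal(0, params.area_jitter),
                         0.2, 0.6))
    area = frac * h * w
    margin = 2.0
    if _shape_extent(pill.shape, 0.2 * h * w) + margin > min(h, w) / 2:
        raise SizingError(
            f"canvas {canvas_size} cannot hold a {pill.shape} pill at 20% area")
    # shrink the draw (never below the 20% floor) until it fits
    while _shape_extent(pill.shape, area) + margin > min(h, w) / 2:
        area *= 0.95

    center = (h / 2 + rng.uniform(-0.04, 0.04) * h,
              w / 2 + rng.uniform(-0.04, 0.04) * w)
    angle = rng.uniform(0, np.pi)
    mask = _shape_mask(pill.shape, area, (h, w), center, angle)

    base = np.asarray(pill.base_rgb, dtype=float) / 255.0
    bg_level = params.bg_black if condition.background == "black" else params.bg_white
    auto_gain = 1.0 - params.auto_exposure_coeff * (bg_level - params.bg_black)

    scene = np.empty((h, w, 3), dtype=float)
    scene[:] = bg_level
    scene[mask] = base * auto_gain

    n_pill = int(mask.sum())
    imprint = np.zeros_like(mask)
    if pill.has_imprint:
        imprint = _imprint_mask(mask, center, angle, float(n_pill),
                                params.imprint_area_frac)
        scene[imprint] *= 1.0 - params.imprint_depth

    # ground truth: exact mean surface colour before illumination effects
    imprint_frac = imprint.sum() / max(n_pill, 1)
    truth = base * (1.0 - params.imprint_depth * imprint_frac) * 255.0

    if condition.flash == "on":
        scene *= params.flash_gain
        r_eff = np.sqrt(area / np.pi)
        hc = (center[0] - 0.3 * r_eff * rng.uniform(0.5, 1.5),
              center[1] + 0.3 * r_eff * rng.uniform(-1.0, 1.0))
        rr, cc = np.mgrid[0:h, 0:w].astype(float)
        d2 = (rr - hc[0]) ** 2 + (cc - hc[1]) ** 2
        sigma = params.flash_sigma_frac * r_eff
        scene += params.flash_strength * np.exp(-d2 / (2 * sigma ** 2))[..., None]

    scene *= 2.0 ** condition.ev

    if params.noise_sigma > 0:
        scene = scene + rng.normal(0, params.noise_sigma / 255.0, scene.shape)

    image = np.clip(np.rint(scene * 255.0), 0, 255).astype(np.uint8)
    return ImageRecord(image=image, label=pill.label, condition=condition.name,
                       truth_mask=mask, truth_rgb=tuple(truth), seed=seed)


def derive_seed(seed: int, label: int, cond_index: int, replicate: int) -> int:
    """Stable per-image child seed below 2^31."""
    ss = np.random.SeedSequence([seed, label, cond_index, replicate])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_records(catalog: Sequence[PillClass],
                     conditions: Sequence[ConditionSpec],
                     n_per_cell: int, seed: int,
                     canvas_size: tuple[int, int] = (128, 128),
                     params: RenderParams | None = None) -> list[ImageRecord]:
    """Render the full factorial in memory: one list entry per image,
    conditions outermost, pills inner, replicates innermost."""
    if n_per_cell < 1:
        raise ValueError(f"n_per_cell must be ≥ 1, got {n_per_cell}")
    records = []
    for ci, cond in enumerate(conditions):
        for pill in catalog:
            for rep in range(n_per_cell):
                records.append(render_image(
                    pill, cond, canvas_size,
                    seed=derive_seed(seed, pill.label, ci, rep), params=params))
    return records


def generate_dataset(catalog: Sequence[PillClass],
                     conditions: Sequence[ConditionSpec] | None,
                     n_per_cell: int, seed: int, out_dir: str | os.PathLike,
                     canvas_size: tuple[int, int] = (128, 128),
                     params: RenderParams | None = None) -> Path:
    """Write PNG images, truth-mask PNGs and a CSV manifest.

    conditions defaults to the 12-condition grid plus the reference set.
    The manifest has header ``path,label,condition,seed`` (UTF-8, LF),
    one row per image, in deterministic generation order; truth masks
    are stored under ``masks/`` mirroring the image paths.

    Returns the manifest path.
    """
    if conditions is None:
        conditions = list(condition_grid()) + [reference_condition()]
    out = Path(out_dir)
    try:
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc

    records = generate_records(catalog, conditions, n_per_cell, seed,
                               canvas_size, params)
    manifest = out / "manifest.csv"
    idx = 0
    with open(manifest, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["path", "label", "condition", "seed"])
        for ci, cond in enumerate(conditions):
            (out / "images" / cond.name).mkdir(exist_ok=True)
            (out / "masks" / cond.name).mkdir(exist_ok=True)
            for pill in catalog:
                for rep in range(n_per_cell):
                    rec = records[idx]
                    idx += 1
                    rel = f"images/{cond.name}/{pill.label:02d}_{rep}.png"
                    iio.imwrite(out / rel, rec.image)
                    iio.imwrite(out / "masks" / cond.name / f"{pill.label:02d}_{rep}.png",
                                rec.truth_mask.astype(np.uint8) * 255)
                    writer.writerow([rel, pill.label, cond.name, rec.seed])
    return manifest


def params_dict(params: RenderParams) -> dict:
    """Plain-dict view of RenderParams for provenance logs and YAML."""
    return asdict(params)
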