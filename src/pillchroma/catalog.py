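"""Pill catalog and imaging-condition grid.

The study design crosses 19 pill classes with 12 real-world imaging
conditions (background ∈ {black, white} × flash ∈ {on, off} × exposure
value EV ∈ {−2.0, 0, +2.0}) plus one reference condition (black
background, flash off, EV 0) under which reference images are taken.

The catalog reproduces the published marginal distributions of the 19
reference pills: 7 colour categories (pink 1, blue 5, white 5, yellow 4,
green 1, yellow-green 2, orange 1), 7 shape categories (counts
6, 3, 4, 1, 2, 2, 1) and 4 dosage forms (film-coated 10, sugar-coated 2,
uncoated 6, hard-capsule 1). Base surface colours are drawn from named
per-category RGB gamuts so that e.g. every "blue" pill has a dominant
blue channel, and are pairwise distinct so the classes are separable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

SHAPES = ("round", "oval", "oblong", "capsule", "triangle", "pentagon", "diamond")
COLOR_CATEGORIES = ("pink", "blue", "white", "yellow", "green", "yellow-green", "orange")
DOSAGE_FORMS = ("film-coated", "sugar-coated", "uncoated", "hard-capsule")

#: published marginal counts over the 19-pill reference set
COLOR_COUNTS = {
    "pink": 1, "blue": 5, "white": 5, "yellow": 4,
    "green": 1, "yellow-green": 2, "orange": 1,
}
SHAPE_COUNTS = {
    "round": 6, "oval": 3, "oblong": 4, "capsule": 1,
    "triangle": 2, "pentagon": 2, "diamond": 1,
}
DOSAGE_COUNTS = {
    "film-coated": 10, "sugar-coated": 2, "uncoated": 6, "hard-capsule": 1,
}

CATALOG_SIZE = 19

# Label→colour assignment. The published colour-subgroup figure places
# pills 6, 12, 13, 14, 16 in the yellow-ish group and 5, 7, 11 in the
# green-ish group; with the colour marginals above that reading holds
# when orange is pooled with yellow and yellow-green with green.
_COLOR_BY_LABEL = {
    1: "pink",
    2: "blue", 3: "blue", 4: "blue", 8: "blue", 9: "blue",
    10: "white", 15: "white", 17: "white", 18: "white", 19: "white",
    6: "yellow", 12: "yellow", 13: "yellow", 14: "yellow",
    16: "orange",
    5: "green",
    7: "yellow-green", 11: "yellow-green",
}

# 8-bit sampling gamut per colour category: (lo, hi) per channel.
_GAMUTS = {
    "pink": ((220, 250), (140, 180), (160, 200)),
    "blue": ((40, 110), (90, 160), (185, 245)),
    "white": ((225, 250), (225, 250), (225, 250)),
    "yellow": ((205, 245), (180, 230), (30, 90)),
    "green": ((60, 120), (170, 220), (60, 120)),
    "yellow-green": ((150, 200), (200, 240), (40, 100)),
    "orange": ((230, 250), (120, 170), (20, 70)),
}


@dataclass(frozen=True)
class PillClass:
    """One catalog entry: a pill's class label and physical identifiers."""

    label: int
    shape: str
    color_category: str
    dosage_form: str
    base_rgb: tuple[int, int, int]
    has_imprint: bool

    def __post_init__(self) -> None:
        if not 1 <= self.label <= CATALOG_SIZE:
            raise ValueError(f"label must be in 1..{CATALOG_SIZE}, got {self.label}")
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.color_category not in COLOR_CATEGORIES:
            raise ValueError(f"unknown color category {self.color_category!r}")
        if self.dosage_form not in DOSAGE_FORMS:
            raise ValueError(f"unknown dosage form {self.dosage_form!r}")


@dataclass(frozen=True)
class ConditionSpec:
    """One imaging condition: background colour, flash state and EV."""

    name: str
    background: str  # "black" | "white"
    flash: str       # "on" | "off"
    ev: float        # exposure compensation in stops
    is_reference: bool = False

    def __post_init__(self) -> None:
        if self.background not in ("black", "white"):
            raise ValueError(f"background must be black/white, got {self.background!r}")
        if self.flash not in ("on", "off"):
            raise ValueError(f"flash must be on/off, got {self.flash!r}")
        if self.ev not in (-2.0, 0.0, 2.0):
            raise ValueError(f"ev must be one of -2.0, 0.0, +2.0, got {self.ev}")


def _condition_name(background: str, flash: str, ev: float) -> str:
    b = "B" if background == "black" else "W"
    f = "O" if flash == "on" else "X"
    e = "0" if ev == 0 else f"{ev:+.1f}"
    return f"{b}_{f}_EV{e}"


def condition_grid() -> list[ConditionSpec]:
    """The full factorial of 12 real-world conditions, in the published
    table order (black/flash-on, white/flash-on, black/flash-off,
    white/flash-off; EV −2.0, 0, +2.0 within each block)."""
    grid = []
    for flash in ("on", "off"):
        for background in ("black", "white"):
            for ev in (-2.0, 0.0, 2.0):
                grid.append(ConditionSpec(
                    name=_condition_name(background, flash, ev),
                    background=background, flash=flash, ev=ev,
                ))
    return grid


def reference_condition() -> ConditionSpec:
    """Reference capture condition: black background, flash off, EV 0."""
    return ConditionSpec(name="reference", background="black", flash="off",
                         ev=0.0, is_reference=True)


def parse_condition_name(name: str) -> tuple[str, str, float]:
    """Split a grid condition name into (background, flash, ev)."""
    if name == "reference":
        return ("black", "off", 0.0)
    try:
        b, f, e = name.split("_")
        background = {"B": "black", "W": "white"}[b]
        flash = {"O": "on", "X": "off"}[f]
        ev = float(e.removeprefix("EV"))
    except (ValueError, KeyError) as exc:
        raise ValueError(f"unparseable condition name {name!r}") from exc
    return (background, flash, ev)


def _sample_rgb(category: str, rng: np.random.Generator) -> tuple[int, int, int]:
    lo_hi = _GAMUTS[category]
    while True:
        r, g, b = (int(rng.integers(lo, hi + 1)) for lo, hi in lo_hi)
        if category == "blue" and not (b > r + 40 and b > g + 30):
            continue
        if category == "white" and max(r, g, b) - min(r, g, b) > 15:
            continue
        if category in ("green", "yellow-green") and not (g > r and g > b):
            continue
        if category == "yellow" and not (r > b + 80 and g > b + 80):
            continue
        return (r, g, b)


def build_catalog(seed: int = 0) -> list[PillClass]:
    """Build the deterministic 19-pill catalog for a given seed.

    The categorical assignments (shape, colour category, dosage form)
    are fixed by the published marginals; only the base RGB values and
    the imprint flags are drawn from the seeded generator. Base colours
    are rejected until pairwise Chebyshev distance ≥ 10 so that no two
    classes share a near-identical surface colour.
    """
    rng = np.random.default_rng(seed)

    shape_pool = [s for s in ("round", "oval", "oblong", "triangle", "pentagon", "diamond")
                  for _ in range(SHAPE_COUNTS[s])]
    # label 19 is the hard capsule and takes the capsule shape
    shapes = {19: "capsule"}
    for label, shape in zip([l for l in range(1, 19)], shape_pool):
        shapes[label] = shape

    dosage = {}
    for label in range(1, 20):
        if label == 19:
            dosage[label] = "hard-capsule"
        elif label <= 10:
            dosage[label] = "film-coated"
        elif label <= 12:
            dosage[label] = "sugar-coated"
        else:
            dosage[label] = "uncoated"

    chosen: list[tuple[int, int, int]] = []
    catalog = []
    for label in range(1, 20):
        category = _COLOR_BY_LABEL[label]
        for _ in range(1000):
            rgb = _sample_rgb(category, rng)
            if all(max(abs(a - b) for a, b in zip(rgb, prev)) >= 10 for prev in chosen):
                break
        else:  # pragma: no cover - gamuts are wide enough in practice
            raise RuntimeError("could not draw pairwise-distinct base colours")
        chosen.append(rgb)
        catalog.append(PillClass(
            label=label,
            shape=shapes[label],
            color_category=category,
            dosage_form=dosage[label],
            base_rgb=rgb,
            has_imprint=bool(rng.random() < 0.5),
        ))
    return catalog


def validate_catalog(catalog: Sequence[PillClass]) -> None:
    """Raise ValueError if the catalog violates the published marginals."""
    if len(catalog) != CATALOG_SIZE:
        raise ValueError(f"catalog must have {CATALOG_SIZE} entries, got {len(catalog)}")
    for counts, attr in ((COLOR_COUNTS, "color_category"),
                         (SHAPE_COUNTS, "shape"),
                         (DOSAGE_COUNTS, "dosage_form")):
        observed: dict[str, int] = {}
        for pill in catalog:
            key = getattr(pill, attr)
            observed[key] = observed.get(key, 0) + 1
        if observed != counts:
            raise ValueError(f"{attr} marginals {observed} != expected {counts}")
    if len({p.base_rgb for p in catalog}) != CATALOG_SIZE:
        raise ValueError("base colours are not pairwise distinct")
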