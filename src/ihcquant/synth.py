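"""Synthetic IHC-like scenes with ground truth.

Emulates DAB/hematoxylin-stained epithelium photographed at 20X: nuclei
are filled ellipses at three staining levels - dark brown (highly
stained), light brown (low stained) and blue-purple (counterstain only) -
on a pale background, with per-pixel Gaussian color noise.  The default
palette is chosen so that the L*b product ordering the RDA relies on
holds (strongly stained darkest product, background highest).  Scenes are
deterministic for a fixed seed and every nucleus is recorded as a
ground-truth cell, which makes end-to-end detection, classification and
strata tests self-validating.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .model import (
    AnalysisRegion,
    BasalPoint,
    Cell,
    CellSource,
    ImageRecord,
    StainCategory,
    ValidationError,
)

RGB = tuple[int, int, int]


class CapacityError(ValueError):
    """Requested nuclei do not fit at the spacing constraint."""


@dataclass(frozen=True)
class SynthParams:
    width: int = 512
    height: int = 512
    n_high: int = 10
    n_low: int = 10
    n_none: int = 10
    d_min: float = 14.0
    d_max: float = 26.0
    color_high: RGB = (90, 60, 30)       # dark brown (DAB, strong)
    color_low: RGB = (170, 130, 90)      # light brown (DAB, weak)
    color_none: RGB = (150, 150, 200)    # blue-purple (hematoxylin)
    color_background: RGB = (235, 230, 238)
    color_sd: float = 8.0
    spacing_factor: float = 1.2          # min center spacing = factor * d_max
    blotch_rate: float = 0.0             # expected background-stain blotches
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_high, self.n_low, self.n_none) < 0:
            raise ValidationError("nucleus counts must be >= 0")
        if not (0 < self.d_min < self.d_max):
            raise ValidationError("need 0 < d_min < d_max")
        if not self.spacing_factor * self.d_max > 0:
            raise ValidationError("spacing must be positive")

    @property
    def spacing(self) -> float:
        return self.spacing_factor * self.d_max


@dataclass
class GroundTruth:
    cells: list[Cell] = field(default_factory=list)
    layers: list[Optional[str]] = field(default_factory=list)  # parallel to cells

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["x", "y", "category", "layer"])
            for c, lay in zip(self.cells, self.layers):
                w.writerow([repr(c.x), repr(c.y), c.category.value,
                            lay if lay is not None else ""])

    @classmethod
    def from_csv(cls, path: str | Path) -> "GroundTruth":
        gt = cls()
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                gt.cells.append(Cell(float(row["x"]), float(row["y"]),
                                     StainCategory(row["category"]),
                                     CellSource.MANUAL))
                gt.layers.append(row["layer"] or None)
        return gt


_CLASS_COLORS = {
    StainCategory.HIGH: "color_high",
    StainCategory.LOW: "color_low",
    StainCategory.NONE: "color_none",
}


def _sample_centers(rng: np.random.Generator, n: int, spacing: float,
                    x0: float, x1: float, y0: float, y1: float,
                    existing: list[np.ndarray],
                    max_attempts: int = 10_000) -> list[np.ndarray]:
    centers = list(existing)
    new: list[np.ndarray] = []
    attempts = 0
    while len(new) < n:
        if attempts >= max_attempts:
            raise CapacityError(
                f"could not place {n} nuclei at spacing {spacing:.1f} after "
                f"{max_attempts} attempts; request fewer nuclei")
        attempts += 1
        c = np.array([rng.uniform(x0, x1), rng.uniform(y0, y1)])
        if all(np.hypot(*(c - o)) > spacing for o in centers):
            centers.append(c)
            new.append(c)
    return new


def _paint_ellipse(img: np.ndarray, rng: np.random.Generator,
                   center: np.ndarray, d_eq: float, color: RGB,
                   sd: float) -> None:
    ratio = rng.uniform(0.8, 1.0)
    theta = rng.uniform(0.0, np.pi)
    a = (d_eq / 2.0) / np.sqrt(ratio)   # semi-major; a*b = (d_eq/2)^2
    b = (d_eq / 2.0) * np.sqrt(ratio)
    h, w = img.shape[:2]
    r = int(np.ceil(a)) + 1
    cx, cy = center
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx, dy = xs - cx, ys - cy
    u = (dx * np.cos(theta) + dy * np.sin(theta)) / a
    v2 = (-dx * np.sin(theta) + dy * np.cos(theta)) / b
    inside = u * u + v2 * v2 <= 1.0
    npx = int(inside.sum())
    if npx == 0:
        return
    noise = rng.normal(0.0, sd, size=(npx, 3))
    patch = img[y0:y1, x0:x1]
    patch[inside] = np.clip(np.array(color) + noise, 0, 255)


def render_scene(params: SynthParams = SynthParams()
                 ) -> tuple[ImageRecord, GroundTruth]:
    """Render nuclei at random non-overlapping positions on pale background."""
    rng = np.random.default_rng(params.seed)
    img = np.clip(
        np.array(params.color_background, dtype=np.float64)
        + rng.normal(0.0, params.color_sd, size=(params.height, params.width, 3)),
        0, 255)
    margin = params.d_max / 2.0 + 2.0
    if params.blotch_rate > 0:
        for _ in range(rng.poisson(params.blotch_rate)):
            c = np.array([rng.uniform(0, params.width),
                          rng.uniform(0, params.height)])
            _paint_ellipse(img, rng, c, 3.0 * params.d_max,
                           params.color_low, params.color_sd * 1.5)
    gt = GroundTruth()
    centers: list[np.ndarray] = []
    for cat, n in ((StainCategory.HIGH, params.n_high),
                   (StainCategory.LOW, params.n_low),
                   (StainCategory.NONE, params.n_none)):
        new = _sample_centers(rng, n, params.spacing,
                              margin, params.width - margin,
                              margin, params.height - margin, centers)
        centers.extend(new)
        color = getattr(params, _CLASS_COLORS[cat])
        for c in new:
            d_eq = rng.uniform(params.d_min * 1.1, params.d_max * 0.9)
            _paint_ellipse(img, rng, c, d_eq, color, params.color_sd)
            gt.cells.append(Cell(float(c[0]), float(c[1]), cat,
                                 CellSource.MANUAL))
            gt.layers.append(None)
    return ImageRecord(np.round(img).astype(np.uint8), id="synthetic"), gt


def epithelium_roi_scene(params: SynthParams = SynthParams(),
                         rotation: float = 0.0,
                         ) -> tuple[ImageRecord, AnalysisRegion, BasalPoint,
                                    GroundTruth]:
    """A rotated rectangular epithelium band with nuclei in known thirds.

    The band is centered in the image; the basal side is the long side
    that faces the basal point (placed outside the band).  Each category's
    nuclei are spread round-robin over the three thirds of the band
    thickness, with a 2-px margin from the third boundaries so that layer
    labels are unambiguous, and the ground truth records each nucleus's
    layer.
    """
    rng = np.random.default_rng(params.seed)
    theta = np.deg2rad(rotation)
    cx, cy = params.width / 2.0, params.height / 2.0
    band_len = 0.70 * min(params.width, params.height)
    band_th = 0.36 * min(params.width, params.height)
    u = np.array([np.cos(theta), np.sin(theta)])        # along the band
    v = np.array([-np.sin(theta), np.cos(theta)])       # across (basal -> superior)
    center = np.array([cx, cy])
    basal_edge = center - v * (band_th / 2.0)
    corners = [center - u * band_len / 2 - v * band_th / 2,
               center + u * band_len / 2 - v * band_th / 2,
               center + u * band_len / 2 + v * band_th / 2,
               center - u * band_len / 2 + v * band_th / 2]
    region = AnalysisRegion([(float(p[0]), float(p[1])) for p in corners])
    basal = BasalPoint(*(basal_edge - v * 30.0))

    img = np.clip(
        np.array(params.color_background, dtype=np.float64)
        + rng.normal(0.0, params.color_sd, size=(params.height, params.width, 3)),
        0, 255)
    gt = GroundTruth()
    centers: list[np.ndarray] = []
    layer_names = ("basal", "medial", "superior")
    end_margin = params.d_max / 2.0 + 2.0
    third = band_th / 3.0
    per_layer: dict[str, list[StainCategory]] = {n: [] for n in layer_names}
    for cat, n in ((StainCategory.HIGH, params.n_high),
                   (StainCategory.LOW, params.n_low),
                   (StainCategory.NONE, params.n_none)):
        for i in range(n):
            per_layer[layer_names[i % 3]].append(cat)
    for li, name in enumerate(layer_names):
        lo = li * third + 2.0           # 2-px margin off the third boundaries
        hi = (li + 1) * third - 2.0
        for cat in per_layer[name]:
            placed = False
            for _ in range(10_000):
                s = rng.uniform(-band_len / 2 + end_margin,
                                band_len / 2 - end_margin)
                t = rng.uniform(lo, hi)
                c = basal_edge + u * s + v * t
                if all(np.hypot(*(c - o)) > params.spacing for o in centers):
                    placed = True
                    break
            if not placed:
                raise CapacityError("band too crowded for requested nuclei")
            centers.append(c)
            d_eq = rng.uniform(params.d_min * 1.1, params.d_max * 0.9)
            _paint_ellipse(img, rng, c, d_eq,
                           getattr(params, _CLASS_COLORS[cat]), params.color_sd)
            gt.cells.append(Cell(float(c[0]), float(c[1]), cat,
                                 CellSource.MANUAL))
            gt.layers.append(name)
    return (ImageRecord(np.round(img).astype(np.uint8), id="synthetic-band"),
            region, basal, gt)
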