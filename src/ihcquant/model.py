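"""Domain types shared by every stage of the analysis.

The unit of persistence is the :class:`Overlay`: everything a user decided
about one image (region of analysis, basal point, calibration, diameter
range) together with the detected/curated cells.  Coordinates are 0-based
image coordinates, origin at the top-left corner, x rightward, y downward,
with pixel centers at integer coordinates.  Polygons are stored as open
vertex lists and closed implicitly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Point, Polygon


class ValidationError(ValueError):
    """An object violates a domain invariant."""


class StainCategory(enum.Enum):
    """Three-level DAB staining intensity of a nucleus.

    HIGH and LOW are brown (stained) at two intensities; NONE is the
    hematoxylin counterstain (unstained, bluish) and is the negative class.
    """

    HIGH = "HIGH"
    LOW = "LOW"
    NONE = "NONE"


class CellSource(enum.Enum):
    """Which detection channel produced a cell (or MANUAL for user edits)."""

    RDA_HIGH = "RDA_HIGH"
    RDA_LOW = "RDA_LOW"
    RDA_WS = "RDA_WS"
    EDA = "EDA"
    MANUAL = "MANUAL"


@dataclass
class ImageRecord:
    """8-bit RGB microscopy image plus an identifier (typically its path)."""

    pixels: np.ndarray  # (H, W, 3) uint8
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValidationError("image must be H x W x 3 (RGB)")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValidationError("image must be at least 1 x 1")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValidationError("channel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class Calibration:
    """Spatial calibration in microns per pixel; unset means pixel units."""

    microns_per_pixel: Optional[float] = None

    def __post_init__(self) -> None:
        if self.microns_per_pixel is not None and not self.microns_per_pixel > 0:
            raise ValidationError("microns_per_pixel must be > 0 when set")

    @property
    def is_set(self) -> bool:
        return self.microns_per_pixel is not None


def to_physical(value_px: float, cal: Calibration) -> float:
    """Convert a pixel measure to microns if calibrated, else pass through."""
    if value_px < 0:
        raise ValidationError("pixel value must be non-negative")
    if cal.is_set:
        return value_px * cal.microns_per_pixel
    return value_px


@dataclass
class Cell:
    """A detected nucleus, represented by its centroid point.

    ``x``/``y`` are sub-pixel image coordinates.  ``category`` is None until
    the stain classifier (or the user) labels the cell.
    """

    x: float
    y: float
    category: Optional[StainCategory] = None
    source: CellSource = CellSource.MANUAL


@dataclass
class AnalysisRegion:
    """User-drawn simple polygon delimiting the epithelium to analyse."""

    vertices: Sequence[tuple[float, float]]

    def __post_init__(self) -> None:
        self.vertices = [(float(x), float(y)) for x, y in self.vertices]
        if len(self.vertices) < 3:
            raise ValidationError("region needs at least 3 vertices")
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            raise ValidationError("region polygon must be simple (non-self-intersecting)")
        if not poly.area > 0:
            raise ValidationError("region polygon must have positive area")

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def contains(self, x: float, y: float) -> bool:
        """Boundary-inclusive containment test."""
        return self.polygon().covers(Point(x, y))


@dataclass(frozen=True)
class BasalPoint:
    """Point marked outside the region, on the side of the basal layer."""

    x: float
    y: float


@dataclass(frozen=True)
class DiameterRange:
    """Acceptable nucleus diameter interval, stored in pixels."""

    d_min: float
    d_max: float

    def __post_init__(self) -> None:
        if not (0 < self.d_min < self.d_max):
            raise ValidationError("diameter range requires 0 < d_min < d_max")


@dataclass
class Overlay:
    """The persisted analysis state of one image."""

    image_id: str
    width: int
    height: int
    diameters: DiameterRange
    region: AnalysisRegion
    calibration: Calibration = field(default_factory=Calibration)
    basal: Optional[BasalPoint] = None
    cells: list[Cell] = field(default_factory=list)

    def validate(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValidationError("overlay image dimensions must be positive")
        poly = self.region.polygon()
        for i, c in enumerate(self.cells):
            if not (0 <= c.x < self.width and 0 <= c.y < self.height):
                raise ValidationError(f"cell {i} at ({c.x}, {c.y}) lies outside the image")
            if not poly.covers(Point(c.x, c.y)):
                raise ValidationError(f"cell {i} at ({c.x}, {c.y}) lies outside the region")
        if self.basal is not None and poly.covers(Point(self.basal.x, self.basal.y)):
            raise ValidationError("basal point must lie strictly outside the region")
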