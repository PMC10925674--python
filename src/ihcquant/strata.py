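"""Partition of an epithelial region into basal / medial / superior thirds.

The user marks a basal point outside the region on the basement-membrane
side.  The minimum-area enclosing (rotated) rectangle of the region is
computed; the rectangle side closest to the basal point is the basal
side.  Lines perpendicular to the basal side are swept across the region;
each line's chord through the region is cut at 1/3 and 2/3 of its length
(measured from the basal end), and the two resulting polylines divide the
region into three layer polygons.  Chord thirds measure the local
epithelial thickness, so the partition follows the tissue even when the
region is oblique in the image.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import split as shapely_split
from shapely.ops import unary_union

from .model import AnalysisRegion, BasalPoint, Cell, ValidationError


class NonSimpleEpitheliumError(ValueError):
    """Too many sweep lines cross the contour other than twice."""


class Layer(enum.Enum):
    BASAL = "basal"
    MEDIAL = "medial"
    SUPERIOR = "superior"


@dataclass(frozen=True)
class MinRect:
    """Minimum-area enclosing rectangle; corners in adjacency order,
    counterclockwise (positive shoelace), starting at the corner nearest
    the first region vertex."""

    corners: tuple[tuple[float, float], ...]

    def side(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        a = np.array(self.corners[i % 4])
        b = np.array(self.corners[(i + 1) % 4])
        return a, b

    @property
    def area(self) -> float:
        return Polygon(self.corners).area


def min_area_rect(region: AnalysisRegion) -> MinRect:
    """Rotating-calipers minimum-area rectangle of the region vertices."""
    poly = region.polygon()
    mrr = poly.minimum_rotated_rectangle
    if mrr.geom_type != "Polygon":
        raise ValidationError("region is degenerate (collinear vertices)")
    corners = list(mrr.exterior.coords)[:4]
    # enforce counterclockwise (positive signed area) adjacency order
    xs = np.array([c[0] for c in corners])
    ys = np.array([c[1] for c in corners])
    signed = 0.5 * float(np.sum(xs * np.roll(ys, -1) - np.roll(xs, -1) * ys))
    if signed < 0:
        corners = corners[::-1]
    first = np.array(region.vertices[0])
    start = int(np.argmin([np.hypot(c[0] - first[0], c[1] - first[1])
                           for c in corners]))
    corners = corners[start:] + corners[:start]
    return MinRect(tuple((float(x), float(y)) for x, y in corners))


def closest_rect_side(rect: MinRect, p: BasalPoint) -> int:
    """Index of the rectangle side nearest to p (ties -> lowest index)."""
    pt = Point(p.x, p.y)
    dists = [LineString([rect.side(i)[0], rect.side(i)[1]]).distance(pt)
             for i in range(4)]
    return int(np.argmin(dists))


@dataclass
class StrataPartition:
    basal: Polygon
    medial: Polygon
    superior: Polygon
    n_lines: int
    n_skipped: int = 0
    gap_assignments: int = 0             # cells rescued by nearest-layer fallback

    def layer_polygons(self) -> dict[str, Polygon]:
        return {"basal": self.basal, "medial": self.medial,
                "superior": self.superior}


def _intersection_points(line: LineString, boundary) -> Optional[list[np.ndarray]]:
    """The two crossing points of a sweep line with the contour, or None."""
    inter = line.intersection(boundary)
    if inter.is_empty:
        return None
    pts = []
    geoms = inter.geoms if hasattr(inter, "geoms") else [inter]
    for g in geoms:
        if g.geom_type == "Point":
            pts.append(np.array([g.x, g.y]))
        else:
            return None  # collinear overlap or stranger geometry: skip
    if len(pts) != 2:
        return None
    return pts


def _split_collect(geom, cutter: LineString) -> list[Polygon]:
    polys = [geom] if geom.geom_type == "Polygon" else list(geom.geoms)
    out = []
    for p in polys:
        pieces = shapely_split(p, cutter)
        out.extend(g for g in pieces.geoms if g.geom_type == "Polygon")
    return out


def partition_layers(region: AnalysisRegion, p: BasalPoint,
                     n_lines: int = 100) -> StrataPartition:
    """Divide the region into basal/medial/superior layer polygons.

    Sweep lines that cross the contour in other than two points are
    skipped; if more than 20% are skipped the region is too folded for
    the equal-thirds construction and an error asks the user to redraw.
    """
    if n_lines < 2:
        raise ValidationError("need at least 2 sweep lines")
    if region.contains(p.x, p.y):
        raise ValidationError("basal point must lie outside the region")
    poly = region.polygon()
    boundary = poly.exterior
    rect = min_area_rect(region)
    side_idx = closest_rect_side(rect, p)
    a, b = rect.side(side_idx)            # basal side
    _, c = rect.side((side_idx + 1) % 4)  # next corner past b
    v = b - a
    side_len = float(np.linalg.norm(v))
    v = v / side_len
    n = c - b                             # into the rectangle, perp to basal
    height = float(np.linalg.norm(n))
    n = n / height

    p1s, p2s = [], []
    skipped = 0
    margin = 0.05 * height + 1.0
    for i in range(1, n_lines + 1):
        base = a + v * ((i - 0.5) / n_lines * side_len)
        sweep = LineString([base - n * margin, base + n * (height + margin)])
        pts = _intersection_points(sweep, boundary)
        if pts is None:
            skipped += 1
            continue
        # pc1 = crossing nearest the basal side
        proj = [float(np.dot(q - a, n)) for q in pts]
        (pc1, pc2) = (pts[0], pts[1]) if proj[0] <= proj[1] else (pts[1], pts[0])
        p1s.append(pc1 + (pc2 - pc1) / 3.0)
        p2s.append(pc1 + 2.0 * (pc2 - pc1) / 3.0)
    if skipped > 0.2 * n_lines or len(p1s) < 2:
        raise NonSimpleEpitheliumError(
            f"{skipped}/{n_lines} sweep lines crossed the contour in != 2 "
            "points; the region is not a simple epithelium band - redraw the ROI")

    ext = side_len + margin
    cut1 = LineString([p1s[0] - v * ext, *p1s, p1s[-1] + v * ext])
    cut2 = LineString([p2s[0] - v * ext, *p2s, p2s[-1] + v * ext])

    def _below(cut: LineString, geom) -> bool:
        """Is the piece on the basal side of the cut polyline (locally)?"""
        rp = geom.representative_point()
        q = cut.interpolate(cut.project(rp))
        return float(np.dot(np.array([rp.x - q.x, rp.y - q.y]), n)) < 0

    pieces = _split_collect(poly, cut1)
    basal = unary_union([g for g in pieces if _below(cut1, g)])
    rest = unary_union([g for g in pieces if not _below(cut1, g)])
    pieces2 = _split_collect(rest, cut2)
    medial = unary_union([g for g in pieces2 if _below(cut2, g)])
    superior = unary_union([g for g in pieces2 if not _below(cut2, g)])
    if basal.is_empty or medial.is_empty or superior.is_empty:
        raise NonSimpleEpitheliumError("layer construction produced an empty layer")
    return StrataPartition(basal=basal, medial=medial, superior=superior,
                           n_lines=n_lines, n_skipped=skipped)


def assign_layer(cell: Cell, part: StrataPartition) -> Layer:
    """Layer containing the cell; boundary ties resolve basal-most.

    A cell falling in none of the layers (a numeric sliver between the
    split polygons) is assigned to the nearest layer and counted in
    ``part.gap_assignments``.
    """
    pt = Point(cell.x, cell.y)
    for layer, geom in ((Layer.BASAL, part.basal), (Layer.MEDIAL, part.medial),
                        (Layer.SUPERIOR, part.superior)):
        if geom.covers(pt):
            return layer
    part.gap_assignments += 1
    dists = {Layer.BASAL: part.basal.distance(pt),
             Layer.MEDIAL: part.medial.distance(pt),
             Layer.SUPERIOR: part.superior.distance(pt)}
    return min(dists, key=dists.get)


def layer_vertex_lists(part: StrataPartition) -> dict[str, list[tuple[float, float]]]:
    """Largest-polygon vertex lists for overlay XML export."""
    out = {}
    for name, geom in part.layer_polygons().items():
        if geom.geom_type == "MultiPolygon":
            geom = max(geom.geoms, key=lambda g: g.area)
        out[name] = [(float(x), float(y)) for x, y in geom.exterior.coords[:-1]]
    return out
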