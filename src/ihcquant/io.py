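"""Persistence: overlay XML files, results CSV export, image loading.

Overlay schema (version "1")::

    <overlay version="1">
      <image id="..." width="W" height="H"/>
      <calibration microns_per_pixel="..."/>   (optional)
      <diameters min="..." max="..."/>
      <region><pt x="..." y="..."/>...</region>
      <basal x="..." y="..."/>                 (optional)
      <cells><cell x="..." y="..." category="HIGH" source="RDA_HIGH"/>...</cells>
      <layer name="basal"><pt .../></layer>    (optional, x3)
    </overlay>

Coordinates are serialized with enough digits (repr of float) that a
write/read round trip is the identity.  Unknown elements are ignored so
that version-1 readers tolerate schema extensions such as ``<layer>``.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from lxml import etree
from PIL import Image

from .model import (
    AnalysisRegion,
    BasalPoint,
    Calibration,
    Cell,
    CellSource,
    DiameterRange,
    ImageRecord,
    Overlay,
    StainCategory,
    ValidationError,
)

SCHEMA_VERSION = "1"

RESULTS_HEADER = [
    "image_id", "layer", "n_high", "n_low", "n_none", "n_total",
    "pct_high", "pct_low", "pct_none", "n_positive", "pct_positive",
]


class OverlayParseError(ValueError):
    """Malformed or invariant-violating overlay file."""


def _fmt(v: float) -> str:
    return repr(float(v))


def write_overlay(overlay: Overlay, path: str | Path,
                  layers: Optional[dict[str, list[tuple[float, float]]]] = None) -> None:
    """Serialize an overlay (optionally with strata polygons) to XML."""
    overlay.validate()
    root = etree.Element("overlay", version=SCHEMA_VERSION)
    etree.SubElement(root, "image", id=overlay.image_id,
                     width=str(overlay.width), height=str(overlay.height))
    if overlay.calibration.is_set:
        etree.SubElement(root, "calibration",
                         microns_per_pixel=_fmt(overlay.calibration.microns_per_pixel))
    etree.SubElement(root, "diameters", min=_fmt(overlay.diameters.d_min),
                     max=_fmt(overlay.diameters.d_max))
    region = etree.SubElement(root, "region")
    for x, y in overlay.region.vertices:
        etree.SubElement(region, "pt", x=_fmt(x), y=_fmt(y))
    if overlay.basal is not None:
        etree.SubElement(root, "basal", x=_fmt(overlay.basal.x), y=_fmt(overlay.basal.y))
    cells = etree.SubElement(root, "cells")
    for c in overlay.cells:
        attrs = {"x": _fmt(c.x), "y": _fmt(c.y), "source": c.source.value}
        if c.category is not None:
            attrs["category"] = c.category.value
        etree.SubElement(cells, "cell", **attrs)
    if layers:
        for name, pts in layers.items():
            el = etree.SubElement(root, "layer", name=name)
            for x, y in pts:
                etree.SubElement(el, "pt", x=_fmt(x), y=_fmt(y))
    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8")


def read_overlay(path: str | Path) -> Overlay:
    """Parse and validate an overlay XML file."""
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as e:
        raise OverlayParseError(f"malformed XML in {path}: {e}") from e
    root = tree.getroot()
    if root.tag != "overlay":
        raise OverlayParseError(f"root element is <{root.tag}>, expected <overlay>")
    if root.get("version") != SCHEMA_VERSION:
        raise OverlayParseError(f"unknown schema version {root.get('version')!r}")

    def _one(tag: str, optional: bool = False):
        els = root.findall(tag)
        if not els:
            if optional:
                return None
            raise OverlayParseError(f"missing <{tag}> element")
        return els[0]

    img = _one("image")
    cal_el = _one("calibration", optional=True)
    cal = Calibration(float(cal_el.get("microns_per_pixel"))) if cal_el is not None else Calibration()
    dia = _one("diameters")
    try:
        diameters = DiameterRange(float(dia.get("min")), float(dia.get("max")))
    except (TypeError, ValidationError) as e:
        raise OverlayParseError(f"bad <diameters>: {e}") from e
    region_el = _one("region")
    pts = [(float(p.get("x")), float(p.get("y"))) for p in region_el.findall("pt")]
    try:
        region = AnalysisRegion(pts)
    except ValidationError as e:
        raise OverlayParseError(f"bad <region>: {e}") from e
    basal_el = _one("basal", optional=True)
    basal = BasalPoint(float(basal_el.get("x")), float(basal_el.get("y"))) if basal_el is not None else None
    cells = []
    cells_el = _one("cells")
    for c in cells_el.findall("cell"):
        cat = c.get("category")
        try:
            cells.append(Cell(
                x=float(c.get("x")), y=float(c.get("y")),
                category=StainCategory(cat) if cat is not None else None,
                source=CellSource(c.get("source", "MANUAL")),
            ))
        except (TypeError, KeyError) as e:
            raise OverlayParseError(f"bad <cell> element: {e}") from e
    overlay = Overlay(
        image_id=img.get("id", ""), width=int(img.get("width")), height=int(img.get("height")),
        diameters=diameters, region=region, calibration=cal, basal=basal, cells=cells,
    )
    try:
        overlay.validate()
    except ValidationError as e:
        raise OverlayParseError(f"invariant violation in {path}: {e}") from e
    return overlay


def write_results_csv(results: Iterable, path: str | Path) -> None:
    """Write quantification rows (one per image and layer) as portable CSV.

    Percentages are printed with 2 decimals; comma separator, "." decimal
    point, UTF-8, header row.
    """
    results = list(results)
    if not results:
        raise ValidationError("results must be nonempty")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(RESULTS_HEADER)
        for r in results:
            w.writerow([
                r.image_id, r.layer, r.n_high, r.n_low, r.n_none, r.n_total,
                f"{r.pct_high:.2f}", f"{r.pct_low:.2f}", f"{r.pct_none:.2f}",
                r.n_positive, f"{r.pct_positive:.2f}",
            ])


def load_image(path: str | Path) -> ImageRecord:
    """Load an 8-bit RGB TIFF or PNG image."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
    return ImageRecord(pixels=arr, id=str(path))


def save_image(img: np.ndarray, path: str | Path) -> None:
    """Save an array (grey or RGB, uint8) as PNG/TIFF — used for debug dumps."""
    Image.fromarray(np.asarray(img, dtype=np.uint8)).save(str(path))
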