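"""Merging of detection channels and restriction to the analysis region.

Detections accumulate across the four channels in a fixed precedence
order (RDA_HIGH, RDA_LOW, RDA_WS, EDA); a candidate is suppressed as a
duplicate if it lies within the minimum diameter of any already-kept
cell.  The greedy rule guarantees that all pairwise distances in the
output exceed d_min, and applying it twice changes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from shapely.geometry import Point

from .eda import EdaParams, eda_detect
from .model import AnalysisRegion, Cell, DiameterRange, ImageRecord
from .rda import DetectOption, rda_detect_multi


@dataclass
class PointSetBundle:
    """Per-channel detections, in the fixed precedence order."""

    rda_high: list[Cell] = field(default_factory=list)
    rda_low: list[Cell] = field(default_factory=list)
    rda_ws: list[Cell] = field(default_factory=list)
    eda: list[Cell] = field(default_factory=list)

    def ordered(self) -> list[Cell]:
        return [*self.rda_high, *self.rda_low, *self.rda_ws, *self.eda]


def merge_point_sets(bundle: PointSetBundle, d_min: float) -> list[Cell]:
    """Greedy duplicate suppression across channels.

    Candidates are visited in channel precedence order (within a channel,
    extraction order); one is kept iff its Euclidean distance to every
    already-kept cell is strictly greater than d_min.  Greedy is not a
    maximum independent set, but it is deterministic and respects
    precedence.
    """
    if not d_min > 0:
        raise ValueError("d_min must be positive")
    kept: list[Cell] = []
    kept_xy = np.empty((0, 2))
    for c in bundle.ordered():
        if kept_xy.shape[0]:
            d = np.hypot(kept_xy[:, 0] - c.x, kept_xy[:, 1] - c.y)
            if not (d > d_min).all():
                continue
        kept.append(c)
        kept_xy = np.vstack([kept_xy, [c.x, c.y]])
    return kept


def filter_to_region(cells: list[Cell], region: AnalysisRegion) -> list[Cell]:
    """Keep cells inside or on the boundary of the analysis polygon."""
    poly = region.polygon()
    return [c for c in cells if poly.covers(Point(c.x, c.y))]


def detect_all(img: ImageRecord, rng: DiameterRange,
               channels: tuple[str, ...] = ("high", "low", "ws", "eda"),
               eda_params: EdaParams = EdaParams(),
               region: Optional[AnalysisRegion] = None) -> list[Cell]:
    """Run the selected detection channels, merge, and clip to the region."""
    bundle = PointSetBundle()
    opts = [opt for name, opt in (("high", DetectOption.HIGH),
                                  ("low", DetectOption.LOW),
                                  ("ws", DetectOption.WS)) if name in channels]
    if opts:
        by_opt = rda_detect_multi(img, rng, tuple(opts))
        bundle.rda_high = by_opt.get(DetectOption.HIGH, [])
        bundle.rda_low = by_opt.get(DetectOption.LOW, [])
        bundle.rda_ws = by_opt.get(DetectOption.WS, [])
    if "eda" in channels:
        bundle.eda = eda_detect(img, rng, eda_params)
    merged = merge_point_sets(bundle, rng.d_min)
    if region is not None:
        merged = filter_to_region(merged, region)
    return merged
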