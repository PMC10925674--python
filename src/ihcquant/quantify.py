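"""Evaluation metrics and per-layer positivity quantification.

Detection is scored by matching automatic detections to ground-truth
points one-to-one within a radius; sensitivity Se = 100*TP/(TP+FN),
"specificity" Sp = 100*TP/(TP+FP) (the positive predictive value - the
name follows the field's detection-scoring convention) and average
precision AP = 100*TP/(TP+FP+FN) (the Jaccard index of the detection
sets).  Classification is scored from a confusion matrix: per-class
Se/Sp, overall accuracy and Cohen kappa.  Positivity is the fraction of
stained cells; by default both staining intensities count as positive,
configurable to HIGH only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .classify import ConfusionMatrix, cohen_kappa
from .model import Cell, Overlay, StainCategory, ValidationError
from .strata import Layer, StrataPartition, assign_layer

DEFAULT_POSITIVE = frozenset({StainCategory.HIGH, StainCategory.LOW})


@dataclass(frozen=True)
class DetectionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValidationError("counts must be non-negative")


@dataclass(frozen=True)
class DetectionMetrics:
    """Percentages; None marks an undefined ratio (zero denominator)."""

    se: Optional[float]
    sp: Optional[float]
    ap: Optional[float]


def match_detections(auto: list[Cell], truth: list[Cell],
                     radius: float) -> DetectionCounts:
    """Greedy one-to-one matching in increasing distance order.

    Pairs farther apart than `radius` never match.  TP = matched pairs,
    FP = unmatched automatic detections, FN = unmatched ground truth.
    """
    if not radius > 0:
        raise ValidationError("match radius must be positive")
    if not auto or not truth:
        return DetectionCounts(0, len(auto), len(truth))
    A = np.array([[c.x, c.y] for c in auto])
    T = np.array([[c.x, c.y] for c in truth])
    D = np.hypot(A[:, None, 0] - T[None, :, 0], A[:, None, 1] - T[None, :, 1])
    pairs = [(D[i, j], i, j) for i in range(len(auto)) for j in range(len(truth))
             if D[i, j] <= radius]
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_t: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_a or j in used_t:
            continue
        used_a.add(i)
        used_t.add(j)
        tp += 1
    return DetectionCounts(tp, len(auto) - tp, len(truth) - tp)


def detection_metrics(c: DetectionCounts) -> DetectionMetrics:
    """Se, Sp, AP in percent; undefined ratios are None, never coerced."""
    if c.tp == 0 and c.fp == 0 and c.fn == 0:
        raise ValidationError("all detection counts are zero; metrics undefined")
    se = 100.0 * c.tp / (c.fn + c.tp) if (c.fn + c.tp) > 0 else None
    sp = 100.0 * c.tp / (c.fp + c.tp) if (c.fp + c.tp) > 0 else None
    ap = 100.0 * c.tp / (c.tp + c.fp + c.fn)
    return DetectionMetrics(se, sp, ap)


@dataclass
class ClassificationMetrics:
    se: dict  # per true class, percent (None if empty row)
    sp: dict  # per predicted class, percent (None if empty column)
    accuracy: float
    kappa: float


def classification_metrics(cm: ConfusionMatrix) -> ClassificationMetrics:
    """Per-class Se/Sp, accuracy and kappa from a confusion matrix."""
    m = cm.matrix
    N = cm.total
    if N <= 0:
        raise ValidationError("empty confusion matrix")
    rows, cols = m.sum(axis=1), m.sum(axis=0)
    se = {lab: (100.0 * m[i, i] / rows[i] if rows[i] > 0 else None)
          for i, lab in enumerate(cm.labels)}
    sp = {lab: (100.0 * m[i, i] / cols[i] if cols[i] > 0 else None)
          for i, lab in enumerate(cm.labels)}
    return ClassificationMetrics(se=se, sp=sp,
                                 accuracy=100.0 * float(np.trace(m)) / N,
                                 kappa=cohen_kappa(cm))


def binarize_matrix(cm: ConfusionMatrix,
                    positive: frozenset | set) -> ConfusionMatrix:
    """Collapse a multi-class matrix to positive vs negative groups."""
    pos_idx = [i for i, lab in enumerate(cm.labels) if lab in positive]
    neg_idx = [i for i, lab in enumerate(cm.labels) if lab not in positive]
    if not pos_idx or not neg_idx:
        raise ValidationError("positive set must be a nonempty proper subset")
    m = cm.matrix
    out = np.array([
        [m[np.ix_(pos_idx, pos_idx)].sum(), m[np.ix_(pos_idx, neg_idx)].sum()],
        [m[np.ix_(neg_idx, pos_idx)].sum(), m[np.ix_(neg_idx, neg_idx)].sum()],
    ])
    return ConfusionMatrix(out, labels=["positive", "negative"])


@dataclass
class QuantResult:
    image_id: str
    layer: str                    # "all", "basal", "medial" or "superior"
    n_high: int
    n_low: int
    n_none: int
    n_positive: int

    @property
    def n_total(self) -> int:
        return self.n_high + self.n_low + self.n_none

    def _pct(self, n: int) -> float:
        return 100.0 * n / self.n_total if self.n_total > 0 else 0.0

    @property
    def pct_high(self) -> float:
        return self._pct(self.n_high)

    @property
    def pct_low(self) -> float:
        return self._pct(self.n_low)

    @property
    def pct_none(self) -> float:
        return self._pct(self.n_none)

    @property
    def pct_positive(self) -> float:
        return self._pct(self.n_positive)


def _count(image_id: str, layer: str, cells: list[Cell],
           positive: frozenset | set) -> QuantResult:
    n = {c: 0 for c in StainCategory}
    for cell in cells:
        n[cell.category] += 1
    return QuantResult(
        image_id=image_id, layer=layer,
        n_high=n[StainCategory.HIGH], n_low=n[StainCategory.LOW],
        n_none=n[StainCategory.NONE],
        n_positive=sum(1 for c in cells if c.category in positive))


def quantify(overlay: Overlay, part: Optional[StrataPartition] = None,
             positive: frozenset | set = DEFAULT_POSITIVE) -> list[QuantResult]:
    """Counts and percentages per staining level, globally and per layer.

    Without a strata partition only the global ("all") row is produced.
    Every cell must be categorized; offenders are reported by index.
    """
    missing = [i for i, c in enumerate(overlay.cells) if c.category is None]
    if missing:
        raise ValidationError(
            f"{len(missing)} uncategorized cell(s) at indices {missing[:10]}"
            f"{'...' if len(missing) > 10 else ''}")
    rows = [_count(overlay.image_id, "all", overlay.cells, positive)]
    if part is not None:
        by_layer: dict[Layer, list[Cell]] = {lay: [] for lay in Layer}
        for c in overlay.cells:
            by_layer[assign_layer(c, part)].append(c)
        for lay in (Layer.BASAL, Layer.MEDIAL, Layer.SUPERIOR):
            rows.append(_count(overlay.image_id, lay.value, by_layer[lay],
                               positive))
    return rows
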