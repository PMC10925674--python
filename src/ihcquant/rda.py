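"""Region-detection algorithm (RDA) for DAB-stained nuclei.

Pipeline: the RGB image is converted to 8-bit CIELAB; the per-pixel product
of the L (lightness) and b (yellowness) planes is min-max normalized to an
8-bit grey image whose darkest values mark the most intensely stained
regions; a three-threshold (four-class) Otsu split of that grey image gives
the lowest threshold t1, below which pixels are taken as highly stained;
the resulting binary image seeds a deterministic 4-cluster k-means in Lab
color space whose clusters correspond to background (0), highly stained
(1), low stained (2) and unstained (3) pixels; joined highly stained nuclei
are separated by thresholding the normalized Euclidean distance transform
at the highest Otsu threshold; finally connected regions within the user's
diameter range become cells (their area centroids).

All stages are deterministic: no RNG is involved anywhere.
"""

from __future__ import annotations

import enum
from pathlib import Path
from typing import NamedTuple, Optional

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import measure, morphology

from .model import Cell, CellSource, DiameterRange, ImageRecord


class DegenerateHistogramError(ValueError):
    """Histogram has too few distinct values for a 4-class Otsu split."""


class DetectOption(enum.Enum):
    """Which RDA channel to extract: highly / low / without staining."""

    HIGH = "HIGH"
    LOW = "LOW"
    WS = "WS"


class LabImage(NamedTuple):
    """CIELAB planes encoded per 8-bit convention.

    L is CIE L* rescaled from [0, 100] to [0, 255]; a and b are CIE a*, b*
    offset by +128 and clipped to [0, 255].  The offset keeps all channels
    non-negative, which the L*b product stage requires.
    """

    L: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def stack(self) -> np.ndarray:
        """(H, W, 3) float array of the three planes."""
        return np.stack([self.L, self.a, self.b], axis=-1).astype(np.float64)


class ThresholdTriple(NamedTuple):
    t1: int
    t2: int
    t3: int


def rgb_to_lab(img: ImageRecord) -> LabImage:
    """sRGB (D65) to 8-bit-encoded CIELAB."""
    lab = skcolor.rgb2lab(img.pixels.astype(np.float64) / 255.0)
    L = np.clip(np.round(lab[..., 0] * 255.0 / 100.0), 0, 255).astype(np.uint8)
    a = np.clip(np.round(lab[..., 1] + 128.0), 0, 255).astype(np.uint8)
    b = np.clip(np.round(lab[..., 2] + 128.0), 0, 255).astype(np.uint8)
    return LabImage(L, a, b)


def grey_from_lab(lab: LabImage) -> np.ndarray:
    """Min-max normalize the per-pixel product L*b to [0, 255].

    Stained (brown) pixels are both dark (low L) and blue-shifted (low b),
    so the product is lowest exactly where the stain is strongest.  A
    constant-product image maps to all zeros.
    """
    prod = lab.L.astype(np.float64) * lab.b.astype(np.float64)
    m, M = prod.min(), prod.max()
    if M == m:
        return np.zeros(prod.shape, dtype=np.uint8)
    return np.round(255.0 * (prod - m) / (M - m)).astype(np.uint8)


def _histogram256(values: np.ndarray) -> np.ndarray:
    return np.bincount(values.ravel().astype(np.int64), minlength=256)[:256]


_VALID_TRIPLE_MASK: Optional[np.ndarray] = None


def _valid_triple_mask() -> np.ndarray:
    global _VALID_TRIPLE_MASK
    if _VALID_TRIPLE_MASK is None:
        t = np.arange(1, 256)
        _VALID_TRIPLE_MASK = (t[:, None, None] < t[None, :, None]) & (
            t[None, :, None] < t[None, None, :]
        )
    return _VALID_TRIPLE_MASK


def otsu3_from_hist(hist: np.ndarray) -> ThresholdTriple:
    """Exhaustive 4-class Otsu over a 256-bin histogram.

    Returns the (t1 < t2 < t3) maximizing the between-class variance of the
    classes [0,t1), [t1,t2), [t2,t3), [t3,255]; exact ties resolve to the
    lexicographically smallest triple.
    """
    hist = np.asarray(hist, dtype=np.float64)
    if np.count_nonzero(hist) < 4:
        raise DegenerateHistogramError(
            f"need >= 4 distinct values, found {np.count_nonzero(hist)}"
        )
    v = np.arange(256, dtype=np.float64)
    W = np.concatenate([[0.0], np.cumsum(hist)])          # W[i] = mass below bin i
    S = np.concatenate([[0.0], np.cumsum(hist * v)])      # S[i] = sum of values below i
    # A[lo, hi] = (sum over [lo,hi))^2 / mass over [lo,hi)  (the w*mu^2 term)
    dW = W[None, :] - W[:, None]
    dS = S[None, :] - S[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        A = np.where(dW > 0, dS * dS / np.where(dW > 0, dW, 1.0), 0.0)
    X = A[0, 1:256]            # class [0, t1)
    Y = A[1:256, 1:256]        # classes [t1, t2) and [t2, t3)
    Z = A[1:256, 256]          # class [t3, 255]
    sigma = (X[:, None] + Y)[:, :, None] + Y[None, :, :] + Z[None, None, :]
    sigma[~_valid_triple_mask()] = -np.inf
    i, j, k = np.unravel_index(np.argmax(sigma), sigma.shape)
    return ThresholdTriple(int(i) + 1, int(j) + 1, int(k) + 1)


def otsu3_thresholds(img: np.ndarray) -> ThresholdTriple:
    """4-class Otsu thresholds of an 8-bit grey image."""
    return otsu3_from_hist(_histogram256(np.asarray(img)))


def threshold_below(img: np.ndarray, t: int) -> np.ndarray:
    """Binary image: 255 where pixel < t, else 0."""
    if not (1 <= t <= 255):
        raise ValueError("threshold must be in [1, 255]")
    return np.where(np.asarray(img) < t, 255, 0).astype(np.uint8)


def seeded_kmeans4(lab: LabImage, binary: np.ndarray) -> np.ndarray:
    """Deterministic 4-means on (L, a, b) pixel vectors, seeded from a mask.

    Initial centroids: c0 = mean Lab of mask-black pixels, c1 = mean of
    mask-white pixels, c2/c3 the 1/3 and 2/3 interpolants between them.
    Batch updates (empty clusters keep their centroid) until the largest
    centroid shift drops below 1.0 Lab units or 20 iterations.  Output
    labels are remapped so that 1 is the cluster nearest the white seed,
    0 the one nearest the black seed, 2 the remaining cluster nearer
    cluster 1, and 3 the last one.
    """
    white = np.asarray(binary) == 255
    if not white.any() or white.all():
        raise ValueError("seed mask must contain both white and black pixels")
    X = lab.stack().reshape(-1, 3)
    w = white.ravel()
    c0 = X[~w].mean(axis=0)
    c1 = X[w].mean(axis=0)
    cents = np.stack([c0, c1, c0 + (c1 - c0) / 3.0, c0 + 2.0 * (c1 - c0) / 3.0])
    for _ in range(20):
        d2 = ((X[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
        labels = np.argmin(d2, axis=1)
        new = cents.copy()
        for k in range(4):
            members = labels == k
            if members.any():
                new[k] = X[members].mean(axis=0)
        shift = np.sqrt(((new - cents) ** 2).sum(axis=1)).max()
        cents = new
        if shift < 1.0:
            break
    d2 = ((X[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1)
    # stable channel mapping by proximity to the initial extreme seeds
    order = [-1, -1, -1, -1]  # order[new_label] = converged-centroid index
    remaining = set(range(4))
    i1 = min(remaining, key=lambda k: np.sum((cents[k] - c1) ** 2))
    remaining.discard(i1)
    i0 = min(remaining, key=lambda k: np.sum((cents[k] - c0) ** 2))
    remaining.discard(i0)
    i2 = min(remaining, key=lambda k: np.sum((cents[k] - cents[i1]) ** 2))
    remaining.discard(i2)
    i3 = remaining.pop()
    order[0], order[1], order[2], order[3] = i0, i1, i2, i3
    remap = np.empty(4, dtype=np.uint8)
    for new_label, old in enumerate(order):
        remap[old] = new_label
    return remap[labels].reshape(white.shape)


def cluster_mask(labels: np.ndarray, k: int, close: bool = False) -> np.ndarray:
    """Binary mask of one cluster, optionally closed with a 3x3 square."""
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    mask = (np.asarray(labels) == k)
    if close:
        mask = morphology.closing(mask, morphology.footprint_rectangle((3, 3)))
    return np.where(mask, 255, 0).astype(np.uint8)


def split_joined_high(mask: np.ndarray) -> np.ndarray:
    """Separate touching nuclei by thresholding the distance transform.

    The exact Euclidean distance transform of the mask is normalized to
    [0, 255]; the highest of the three Otsu thresholds of the nonzero
    distance histogram keeps only the cores of the blobs, which breaks
    necks between joined nuclei.  Masks too small to yield a 4-class
    histogram are returned unchanged (nothing to split).
    """
    fg = np.asarray(mask) > 0
    if not fg.any():
        return np.zeros(fg.shape, dtype=np.uint8)
    D = ndimage.distance_transform_edt(fg)
    dmax = D.max()
    if dmax <= 0:
        return np.zeros(fg.shape, dtype=np.uint8)
    Dn = np.round(255.0 * D / dmax).astype(np.uint8)
    hist = _histogram256(Dn[fg])
    try:
        _, _, t3 = otsu3_from_hist(hist)
    except DegenerateHistogramError:
        return np.where(fg, 255, 0).astype(np.uint8)
    return np.where(Dn > t3, 255, 0).astype(np.uint8)


def extract_cells(mask: np.ndarray, rng: DiameterRange,
                  source: CellSource) -> list[Cell]:
    """Connected white regions (8-connected, holes filled) to cells.

    A region of pixel area A has equivalent-circle diameter
    d = 2*sqrt(A/pi); it is kept iff d_min < d < d_max.  The cell point is
    the area centroid of the (filled) region.
    """
    fg = ndimage.binary_fill_holes(np.asarray(mask) > 0)
    labeled = measure.label(fg, connectivity=2)
    cells = []
    for region in measure.regionprops(labeled):
        d = 2.0 * np.sqrt(region.area / np.pi)
        if rng.d_min < d < rng.d_max:
            cy, cx = region.centroid
            cells.append(Cell(x=float(cx), y=float(cy), source=source))
    return cells


_SOURCE_FOR_OPTION = {
    DetectOption.HIGH: CellSource.RDA_HIGH,
    DetectOption.LOW: CellSource.RDA_LOW,
    DetectOption.WS: CellSource.RDA_WS,
}


def _channel_cells(labels: np.ndarray, option: DetectOption,
                   rng: DiameterRange,
                   debug_dir: Optional[Path] = None) -> list[Cell]:
    if option is DetectOption.HIGH:
        mask = cluster_mask(labels, 1, close=False)
        final = split_joined_high(mask)
    elif option is DetectOption.LOW:
        final = cluster_mask(labels, 2, close=True)
    else:
        final = cluster_mask(labels, 3, close=True)
    if debug_dir is not None:
        from .io import save_image
        save_image(final, debug_dir / f"I_o_{option.value}.png")
    return extract_cells(final, rng, _SOURCE_FOR_OPTION[option])


def rda_detect_multi(img: ImageRecord, rng: DiameterRange,
                     options: tuple[DetectOption, ...],
                     debug_dir: Optional[str | Path] = None,
                     ) -> dict[DetectOption, list[Cell]]:
    """Run several RDA channels, sharing the Lab/Otsu/k-means stages.

    Degenerate images (blank or near-constant, so that the grey image has
    fewer than 4 distinct values or thresholding leaves a single phase)
    yield empty lists rather than raising.
    """
    empty = {opt: [] for opt in options}
    lab = rgb_to_lab(img)
    grey = grey_from_lab(lab)
    try:
        t1, _, _ = otsu3_thresholds(grey)
    except DegenerateHistogramError:
        return empty
    binary = threshold_below(grey, t1)
    if not (binary == 255).any() or not (binary == 0).any():
        return empty
    labels = seeded_kmeans4(lab, binary)
    if debug_dir is not None:
        from .io import save_image
        debug_dir = Path(debug_dir)
        debug_dir.mkdir(parents=True, exist_ok=True)
        save_image(grey, debug_dir / "I_grey.png")
        save_image(binary, debug_dir / "I_bin.png")
        save_image(labels * 85, debug_dir / "I_4.png")
    return {opt: _channel_cells(labels, opt, rng, debug_dir) for opt in options}


def rda_detect(img: ImageRecord, rng: DiameterRange, option: DetectOption,
               debug_dir: Optional[str | Path] = None) -> list[Cell]:
    """Full RDA pipeline for a single channel (see :func:`rda_detect_multi`)."""
    return rda_detect_multi(img, rng, (option,), debug_dir=debug_dir)[option]
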